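"""Shared configuration for the numbered analysis drivers.

The cohort emulates the study protocol (8 alternating eyes-closed /
eyes-open blocks per subject, 27 EEG + 16 noEEG channels at 250 Hz) at a
desk scale: 6 subjects, 60-s blocks, 0.5-s epoch step.  Raw EDFs land in
scratch/ (regenerated on demand); result tables in results/.
"""

from pathlib import Path

from neuroproxy.pipeline import PipelineConfig
from neuroproxy.recordings_io import read_recording, write_recording
from neuroproxy.synthdata import SimulationConfig, generate_cohort

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"

MASTER_SEED = 20_240_101


def cohort_config() -> PipelineConfig:
    sim = SimulationConfig(n_subjects=6, block_length=60.0, seed=MASTER_SEED)
    return PipelineConfig(sim=sim, step=0.5)


def load_or_simulate_cohort(cfg: PipelineConfig):
    """Read the EDF cohort written by 01_simulate_cohort, else regenerate."""
    paths = sorted(COHORT_DIR.glob("subject_*.edf"))
    if paths:
        return [read_recording(p) for p in paths]
    return generate_cohort(cfg.sim)


def write_cohort(recordings) -> None:
    COHORT_DIR.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        write_recording(rec, COHORT_DIR / f"subject_{rec.meta['subject']:02d}.edf")
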