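"""Simulate the synthetic cohort and persist it as EDF + sidecar files.

Each subject gets 4 eyes-closed (OC) and 4 eyes-open (OA) blocks in
seeded random order, a personal alpha frequency on the 0.25 Hz grid, and
artifact transients at the default rates.  Ground truth goes into the
sidecars; the printed table is the reference for the later drivers.
"""

from _common import cohort_config, write_cohort, COHORT_DIR

from neuroproxy.synthdata import generate_cohort


def main() -> None:
    cfg = cohort_config()
    recordings = generate_cohort(cfg.sim)
    write_cohort(recordings)
    print(f"wrote {len(recordings)} recordings to {COHORT_DIR}\n")
    print("subject  true IAF (Hz)  block order")
    for rec in recordings:
        meta = rec.meta
        print(f"{meta['subject']:>7}  {meta['true_iaf']:>13.2f}  "
              f"{' '.join(meta['block_order'])}")


if __name__ == "__main__":
    main()
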