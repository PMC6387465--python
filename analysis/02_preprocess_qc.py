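"""Filter, epoch, and apply the artifact-rejection rules; report retention.

The +-100 uV amplitude rule and the 10 uV/s trend rule drop whole epochs
across all channels.  With the default artifact rates retention sits near
97-98% of the segmented epochs, comparable to the study protocol's
reported average.
"""

import pandas as pd

from _common import RESULTS, cohort_config, load_or_simulate_cohort

from neuroproxy.preprocess import (bandpass, drop_flagged, flag_amplitude,
                                   flag_trend, segment_epochs)


def main() -> None:
    cfg = cohort_config()
    rows = []
    for rec in load_or_simulate_cohort(cfg):
        filtered = bandpass(rec, cfg.filter)
        eps = segment_epochs(filtered, cfg.epoch_length, cfg.step)
        eps = flag_trend(flag_amplitude(eps, cfg.amplitude_limit),
                         cfg.slope_limit)
        clean = drop_flagged(eps)
        n_events = len(rec.meta.get("artifact_events", []))
        rows.append({"subject": rec.meta["subject"],
                     "epochs_total": eps.n_epochs,
                     "epochs_retained": clean.n_epochs,
                     "retention": clean.n_epochs / eps.n_epochs,
                     "injected_events": n_events})
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "epoch_retention.csv", index=False)
    print(df.to_string(index=False))
    print(f"\nmean retention: {df.retention.mean():.3f}")
    print(f"wrote {RESULTS / 'epoch_retention.csv'}")


if __name__ == "__main__":
    main()
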