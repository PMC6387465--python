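"""Condition-mean spectra and per-channel IAF estimates vs ground truth.

For every subject the mean eyes-closed spectrum of each channel is scanned
for its alpha peak (7.5-12.5 Hz); the table shows that posterior EEG
channels and the volume-conduction-coupled noEEG channels recover the
subject's true IAF exactly on the 0.25 Hz grid, while uncoupled channels
do not.
"""

import pandas as pd

from _common import RESULTS, cohort_config, load_or_simulate_cohort

from neuroproxy.pipeline import process_subject


def main() -> None:
    cfg = cohort_config()
    rows = []
    for rec in load_or_simulate_cohort(cfg):
        a = process_subject(rec, cfg)
        for ch, est in a.iaf_by_channel.items():
            rows.append({"subject": a.subject, "channel": ch,
                         "iaf": est.value, "degenerate": est.degenerate,
                         "true_iaf": a.true_iaf,
                         "exact": est.value == a.true_iaf})
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "iaf_by_channel.csv", index=False)

    check = df[df.channel.isin(["Oz", "O1", "O2", "Neck4", "Neck2", "WrL2"])]
    print(check.pivot(index="subject", columns="channel",
                      values="iaf").to_string())
    print("\ntrue IAF per subject:")
    print(df.groupby("subject").true_iaf.first().to_string())
    rate = df[df.channel.isin(["Oz", "Neck4"])]["exact"].mean()
    print(f"\nexact recovery rate at Oz/Neck4: {rate:.2f}")
    print(f"wrote {RESULTS / 'iaf_by_channel.csv'}")


if __name__ == "__main__":
    main()
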