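"""Score the detector against a local copy of an annotated ECG database.

Optional: requires the `wfdb` extra and a local directory of WFDB records
(.hea/.dat/.atr).  Produces one benchmark-style row per record:
record, n_ref, TP, FN, FP, Se, Sp, FDR, FNR, rr_mean, rr_sigma, qrs_mean,
qrs_sigma.

Usage:  python scripts/run_mitbih.py /path/to/records 100 101 ... [--tolerance 0.15]
"""

from __future__ import annotations

import argparse
import csv
import sys
from pathlib import Path

from qrsgram import confusion_rates, detect, match_beats, rr_intervals, summarize
from qrsgram.io import read_wfdb_record


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("database_dir", type=Path)
    ap.add_argument("records", nargs="+", help="record names, e.g. 100 101 ...")
    ap.add_argument("--tolerance", type=float, default=0.15, help="match window (s)")
    ap.add_argument("--out", type=Path, default=Path("mitbih_results.csv"))
    args = ap.parse_args()

    rows = []
    for name in args.records:
        sig, ann = read_wfdb_record(args.database_dir / name)
        if ann is None:
            print(f"{name}: no annotations, skipped", file=sys.stderr)
            continue
        res = detect(sig)
        tp, fp, fn = match_beats(res.r_peaks, ann.indices, args.tolerance, sig.fs)
        rep = confusion_rates(tp, fp, fn)
        s = summarize(rr_intervals(res.r_peaks, sig.fs), res.qrs_durations_s)
        rows.append(
            [name, tp + fn, tp, fn, fp, rep.se_2dp, rep.sp_2dp, rep.fdr_2dp, rep.fnr_2dp,
             round(s.rr_mean or 0, 2), round(s.rr_sigma or 0, 2),
             round(s.qrs_mean or 0, 2), round(s.qrs_sigma or 0, 2)]
        )
        print(f"{name}: Se={rep.se_2dp} Sp={rep.sp_2dp}")

    with open(args.out, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["record", "n_ref", "TP", "FN", "FP", "Se", "Sp", "FDR", "FNR",
                    "rr_mean", "rr_sigma", "qrs_mean", "qrs_sigma"])
        w.writerows(rows)
    print(f"wrote {args.out}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
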