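#!/usr/bin/env python
"""Evaluate both pipelines on a local copy of the PhysioNet Fantasia database.

The Fantasia database (40 two-channel records, f1y01-f1y10, f1o01-f1o10,
f2y01-f2y10, f2o01-f2o10, sampled at 250 Hz with ECG beat annotations in
``.ecg`` files) must be downloaded separately from PhysioNet; this script
only reads a local directory.  For each record it

* runs heartbeat detection on the respiration channel and scores the
  detected beats against the supplied annotations (sensitivity, precision,
  true/false-positive and T-wave percentages, windowed heart-rate MAE/PE/
  NRMSE/Pearson/concordance), and
* reconstructs the composite ECG-derived respiration and scores its
  inspiration peaks against the respiration channel's reference peaks,
  including the 32-s best-lag waveform correlation.

Per-record reports and the across-record averages are written as a single
JSON file mirroring the ``cardioresp eval`` report schema.

Usage:
    python scripts/fantasia_eval.py --data-dir /path/to/fantasia \
        --out results/fantasia_report.json [--records f1y01 f1y02 ...]
"""

from __future__ import annotations

import argparse
import json
import warnings
from pathlib import Path

import numpy as np

from cardioresp.edr import preprocess_reference_respiration, run_edr
from cardioresp.evaluation import (
    classify_beats,
    compute_metrics,
    waveform_correlation,
    window_rates,
)
from cardioresp.io_formats import read_annotations, read_wfdb
from cardioresp.rdc import run_rdc

ALL_RECORDS = [
    f"f{gen}{age}{i:02d}"
    for gen in (1, 2)
    for age in ("y", "o")
    for i in range(1, 11)
]


def evaluate_record(base: Path) -> dict:
    record = read_wfdb(base.with_suffix(".hea"))
    names = {n.upper(): n for n in record.signals}
    ecg = record.signals[names.get("ECG", list(record.signals)[0])]
    resp = record.signals[names.get("RESP", list(record.signals)[-1])]
    reference = read_annotations(base.with_suffix(".ecg"), "wfdb_ann", record.fs)
    span = (0.0, record.duration)
    out: dict = {}

    res = run_rdc(resp)
    rep = classify_beats(res.beat_times, reference, record.fs)
    out["rdc"] = rep.summary()
    out["rdc"]["low_confidence"] = res.low_confidence
    n_ref = len(reference)
    out["rdc"]["true_positive_pct"] = 100.0 * rep.tp / n_ref
    out["rdc"]["false_positive_pct"] = 100.0 * rep.fp / n_ref
    out["rdc"]["t_wave_pct"] = 100.0 * rep.t_wave / n_ref
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = compute_metrics(
            window_rates(reference, span), window_rates(res.beat_times, span)
        )
    out["rdc_hr_metrics"] = {
        "mae": m.mae, "pe": m.pe, "nrmse": m.nrmse,
        "rho_p": m.rho_p, "p_value": m.p_value, "rho_c": m.rho_c, "n": m.n,
    }

    comp, brep = run_edr(ecg, resp)
    out["edr"] = brep.summary()
    out["edr"]["phase_shift_s"] = comp.phase_shift
    ref_filt, ref_peaks = preprocess_reference_respiration(resp)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rr = compute_metrics(
            window_rates(ref_peaks, span), window_rates(comp.breath_peaks, span)
        )
    out["edr_rr_metrics"] = {
        "mae": rr.mae, "pe": rr.pe, "nrmse": rr.nrmse,
        "rho_p": rr.rho_p, "p_value": rr.p_value, "rho_c": rr.rho_c, "n": rr.n,
    }
    wc = waveform_correlation(ref_filt, comp.composite)
    out["edr_waveform_correlation"] = wc["mean_correlation"]
    return out


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, required=True,
                    help="Directory holding the Fantasia .hea/.dat/.ecg files.")
    ap.add_argument("--out", type=Path, required=True)
    ap.add_argument("--records", nargs="*", default=None,
                    help="Record names (default: all 40).")
    args = ap.parse_args()

    names = args.records or ALL_RECORDS
    reports: dict[str, dict] = {}
    for name in names:
        base = args.data_dir / name
        if not base.with_suffix(".hea").exists():
            print(f"skipping {name}: header not found")
            continue
        try:
            reports[name] = evaluate_record(base)
            print(f"{name}: rdc sens "
                  f"{reports[name]['rdc']['sensitivity']:.3f}, edr sens "
                  f"{reports[name]['edr']['sensitivity']:.3f}")
        except Exception as exc:
            reports[name] = {"error": f"{type(exc).__name__}: {exc}"}
            print(f"{name}: failed ({exc})")

    ok = [r for r in reports.values() if "error" not in r]
    averages = {}
    if ok:
        for section in ("rdc", "edr"):
            keys = [k for k, v in ok[0][section].items()
                    if isinstance(v, (int, float)) and v is not None]
            averages[section] = {
                k: float(np.mean([r[section][k] for r in ok
                                  if r[section][k] is not None]))
                for k in keys
            }
    payload = {"records": reports, "averages": averages, "n_records": len(ok)}
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


if __name__ == "__main__":
    main()
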