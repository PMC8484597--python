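"""Serialization of verification reports and histograms.

JSON carries full float precision (repr round-trips doubles exactly);
the text rendering mirrors the six-decimal-digit convention of the
reference tables.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np

from .verification import PathStats, TestResult, VerificationReport

__all__ = [
    "report_to_dict",
    "report_from_dict",
    "write_report",
    "render_text_table",
    "write_histogram_csv",
    "dump_records_csv",
]


def report_to_dict(report: VerificationReport, config_echo: Optional[dict] = None) -> dict:
    return {
        "alpha": report.alpha,
        "m_tests": report.m,
        "expected_rejections": report.expected_rejections,
        "observed_rejections": report.observed_rejections,
        "rejection_pvalue": report.rejection_pvalue,
        "n_capped": report.n_capped,
        "ip_valid": report.ip_valid,
        "ip_warnings": list(report.ip_warnings),
        "passed": report.passed,
        "rows": [
            {
                "label": label,
                "n": s.n,
                "mean_mm": s.mean,
                "sd_mm": s.sd,
                "standard_error_mm": s.standard_error,
                "reference_mm": r,
                "t": t.t,
                "p": t.p,
                "tails": t.tails,
                "significant": t.significant,
            }
            for label, s, r, t in zip(
                report.labels, report.stats, report.references, report.tests
            )
        ],
        "config": config_echo or {},
    }


def report_from_dict(payload: dict) -> VerificationReport:
    rows = payload["rows"]
    return VerificationReport(
        labels=tuple(r["label"] for r in rows),
        stats=tuple(PathStats(n=r["n"], mean=r["mean_mm"], sd=r["sd_mm"]) for r in rows),
        references=tuple(r["reference_mm"] for r in rows),
        tests=tuple(
            TestResult(
                reference=r["reference_mm"],
                t=r["t"],
                p=r["p"],
                tails=r["tails"],
                alpha=payload["alpha"],
            )
            for r in rows
        ),
        alpha=payload["alpha"],
        n_capped=payload["n_capped"],
        ip_valid=payload["ip_valid"],
        ip_warnings=tuple(payload["ip_warnings"]),
        passed=payload["passed"],
        rejection_pvalue=payload["rejection_pvalue"],
    )


def write_report(report: VerificationReport, json_path, config_echo: Optional[dict] = None) -> None:
    payload = report_to_dict(report, config_echo)
    Path(json_path).parent.mkdir(parents=True, exist_ok=True)
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def render_text_table(report: VerificationReport) -> str:
    """Human-readable table, means to six decimal digits."""
    lines = [
        f"{'quantity':<10} {'N':>10} {'<L> (mm)':>12} {'ref (mm)':>12} "
        f"{'se (mm)':>12} {'t':>8} {'p':>8}"
    ]
    for label, s, r, t in zip(report.labels, report.stats, report.references, report.tests):
        lines.append(
            f"{label:<10} {s.n:>10d} {s.mean:>12.6f} {r:>12.6f} "
            f"{s.standard_error:>12.6f} {t.t:>8.2f} {t.p:>8.4f}"
        )
    lines.append(
        f"rejections: {report.observed_rejections} observed vs "
        f"{report.expected_rejections:.2f} expected (m={report.m}, alpha={report.alpha}); "
        f"capped={report.n_capped}; overall: {'PASS' if report.passed else 'FAIL'}"
    )
    return "\n".join(lines)


def dump_records_csv(medium, n_photons: int, seed: int, path) -> None:
    """Per-photon trajectory dump (off by default in runs): columns
    L_mm, l_1..l_K, n_scat, entered.  Re-traces each photon's
    deterministic substream, so the dump matches the tallies of a
    run_ensemble call with the same seed."""
    from .transport import simulate_photon

    k = medium.n_layers
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("L_mm," + ",".join(f"l_{i}" for i in range(1, k + 1)) + ",n_scat,entered\n")
        for i in range(n_photons):
            rec = simulate_photon(medium, seed=seed, photon_index=i)
            parts = ",".join(repr(float(x)) for x in rec.partial_paths)
            fh.write(
                f"{rec.total_path!r},{parts},{rec.n_scatterings},{int(rec.entered)}\n"
            )


def write_histogram_csv(centers: np.ndarray, density: np.ndarray, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("bin_center_mm,density_per_mm\n")
        for c, d in zip(centers, density):
            fh.write(f"{float(c)!r},{float(d)!r}\n")
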