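"""FNR-corrected mutation rate and exact Poisson confidence interval.

    mu = (m / C) * (inserted / detected)

with m confirmed de novo mutations, C callable sites (diploid-doubled),
and inserted/detected the spike-in counts. The 95% CI treats m as a
Poisson count with exact (Garwood, chi-square) bounds, scaling the FNR
correction and 1/C as constants:

    lower = chi2.ppf(alpha/2, 2m) / 2        (0 when m = 0)
    upper = chi2.ppf(1 - alpha/2, 2m + 2) / 2
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

from scipy.stats import chi2


def poisson_exact_ci(k: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact two-sided CI bounds for a Poisson mean, on the count scale."""
    if k < 0 or int(k) != k:
        raise ValueError("k must be a non-negative integer")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    lower = 0.0 if k == 0 else float(chi2.ppf(alpha / 2, 2 * k) / 2)
    upper = float(chi2.ppf(1 - alpha / 2, 2 * k + 2) / 2)
    return lower, upper


def round_sig(x: float, digits: int = 3) -> float:
    """Round to significant figures (display convention; machine
    outputs keep full precision)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + digits - 1)


@dataclass
class RateEstimate:
    m: int
    callable_sites: float
    inserted: int
    detected: int
    mu: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05

    @property
    def correction(self) -> float:
        return self.inserted / self.detected

    @property
    def fnr(self) -> float:
        return (self.inserted - self.detected) / self.inserted


def estimate_rate(
    m: int,
    callable_sites: float,
    inserted: int,
    detected: int,
    alpha: float = 0.05,
) -> RateEstimate:
    if m < 0:
        raise ValueError("m must be >= 0")
    if callable_sites <= 0:
        raise ValueError("callable_sites must be positive")
    if detected <= 0:
        raise ValueError("correction undefined: no synthetic mutations detected")
    scale = (inserted / detected) / callable_sites
    lo, hi = poisson_exact_ci(m, alpha)
    return RateEstimate(
        m=m,
        callable_sites=callable_sites,
        inserted=inserted,
        detected=detected,
        mu=m * scale,
        ci_low=lo * scale,
        ci_high=hi * scale,
        alpha=alpha,
    )


def render_report(
    outdir: str | Path,
    paternity: Any = None,
    funnel: Any = None,
    candidates: Any = None,
    callable_summary: Any = None,
    fnr: Any = None,
    rate: RateEstimate | None = None,
) -> dict:
    """Assemble the run's machine-readable summary (JSON + TSVs).

    Every stage output present is written; the JSON records the
    provenance of each number entering the rate formula. Missing
    required stages for the rate section are fatal.
    """
    from .detect import candidates_frame

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"schema_version": 1}
    if paternity is not None:
        paternity.kinship.to_csv(outdir / "kinship.tsv", sep="\t", index=False)
        paternity.concordance.table.to_csv(
            outdir / "mendelian_concordance.tsv", sep="\t", index=False
        )
        report["father"] = paternity.father_id
        report["rank_test_p"] = paternity.rank_test.p_values
    if funnel is not None:
        funnel.to_frame().to_csv(outdir / "funnel.tsv", sep="\t", index=False)
        report["funnel"] = funnel.counts
    if candidates is not None:
        candidates_frame(candidates).to_csv(
            outdir / "candidates.tsv", sep="\t", index=False
        )
        report["n_candidates"] = len(candidates)
    if callable_summary is not None:
        callable_summary.per_trio.to_csv(
            outdir / "callable_per_trio.tsv", sep="\t", index=False
        )
        report["callable_total"] = callable_summary.total
        report["doubling_factor"] = callable_summary.doubling_factor
    if fnr is not None:
        report["fnr"] = {
            "inserted": fnr.inserted,
            "inserted_callable": fnr.inserted_callable,
            "detected": fnr.detected,
            "fnr": fnr.fnr,
        }
    if rate is not None:
        for name, val in (
            ("callable_summary", callable_summary),
            ("fnr", fnr),
        ):
            if val is None:
                raise ValueError(f"rate section requires stage output {name!r}")
        report["rate"] = asdict(rate)
        report["rate_display"] = {
            "mu": round_sig(rate.mu),
            "ci_low": round_sig(rate.ci_low),
            "ci_high": round_sig(rate.ci_high),
        }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
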