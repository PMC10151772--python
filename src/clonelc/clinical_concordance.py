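"""Serum free-light-chain restriction and clone/clinic concordance.

The serum kappa/lambda free-light-chain (FLC) ratio is compared to the
reference range 0.26–1.65: a ratio above the range indicates kappa
restriction, below it lambda restriction, inside it no restriction. When the
FLC ratio is normal or unavailable, the M-protein light-chain type (from
immunofixation/electrophoresis) is used as a fallback. The resolved
restriction is then compared with the locus of the sample's major clone
(IGK ↔ kappa, IGL ↔ lambda).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .config import DEFAULT_CONFIG, AnalysisConfig
from .io_formats import ClinicalRecordRow

_LOCUS_OF = {"kappa": "IGK", "lambda": "IGL"}


@dataclass
class ConcordanceResult:
    sample_id: str
    flc_ratio: Optional[float]      # may be +inf when lambda = 0; None when missing
    restriction: str                # kappa | lambda | normal | indeterminate
    source: str                     # flc | mprotein | none
    clone_locus: Optional[str]      # IGK | IGL
    status: str                     # concordant | discordant | indeterminate
    mprotein_matches_clone: Optional[bool] = None


def flc_restriction(
    serum_kappa: Optional[float],
    serum_lambda: Optional[float],
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> tuple[Optional[float], str]:
    """Kappa/lambda ratio and the restriction it implies.

    Thresholds are strict: ratio > 1.65 → kappa, ratio < 0.26 → lambda,
    boundary values map to normal. A zero lambda with measurable kappa gives
    an infinite ratio (kappa-restricted); missing values give indeterminate.
    """
    if serum_kappa is None or serum_lambda is None:
        return None, "indeterminate"
    if serum_lambda == 0:
        if serum_kappa > 0:
            return math.inf, "kappa"
        return None, "indeterminate"
    ratio = serum_kappa / serum_lambda
    if ratio > config.flc_ratio_high:
        return ratio, "kappa"
    if ratio < config.flc_ratio_low:
        return ratio, "lambda"
    return ratio, "normal"


def resolve_restriction(
    record: ClinicalRecordRow,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> tuple[str, str, Optional[float]]:
    """Resolve a sample's light-chain restriction with its evidence source.

    An abnormal FLC ratio wins; a normal or missing ratio falls back to the
    M-protein light-chain type when one was identified. Returns
    ``(restriction, source, ratio)``.
    """
    ratio, flc = flc_restriction(record.serum_kappa, record.serum_lambda, config)
    if flc in ("kappa", "lambda"):
        return flc, "flc", ratio
    if record.mprotein_lc in ("kappa", "lambda"):
        return record.mprotein_lc, "mprotein", ratio
    if flc == "normal":
        return "normal", "flc", ratio
    return "indeterminate", "none", ratio


def concordance(
    clone_locus: Optional[str],
    record: ClinicalRecordRow,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> ConcordanceResult:
    """Compare the clone's locus with the resolved clinical restriction.

    A normal FLC ratio without M-protein fallback and any missing-data case
    are indeterminate, never counted for or against concordance.
    """
    restriction, source, ratio = resolve_restriction(record, config)
    if clone_locus is None or restriction in ("normal", "indeterminate"):
        status = "indeterminate"
    elif _LOCUS_OF.get(restriction) == clone_locus:
        status = "concordant"
    else:
        status = "discordant"
    mprot_match = None
    if record.mprotein_lc in ("kappa", "lambda") and clone_locus is not None:
        mprot_match = _LOCUS_OF[record.mprotein_lc] == clone_locus
    return ConcordanceResult(
        sample_id=record.sample_id, flc_ratio=ratio, restriction=restriction,
        source=source, clone_locus=clone_locus, status=status,
        mprotein_matches_clone=mprot_match,
    )


@dataclass
class ConcordanceSummary:
    n_total: int
    n_evaluable: int
    n_concordant: int
    n_discordant: int
    percent_concordant: Optional[float]  # 1 dp; None when nothing evaluable


def cohort_concordance_summary(results: Sequence[ConcordanceResult]) -> ConcordanceSummary:
    """Percentage of concordant calls among evaluable (non-indeterminate) samples."""
    evaluable = [r for r in results if r.status != "indeterminate"]
    n_conc = sum(1 for r in evaluable if r.status == "concordant")
    pct = round(100.0 * n_conc / len(evaluable), 1) if evaluable else None
    return ConcordanceSummary(
        n_total=len(results), n_evaluable=len(evaluable),
        n_concordant=n_conc, n_discordant=len(evaluable) - n_conc,
        percent_concordant=pct,
    )
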