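"""Per-nucleus two-channel intensity correlation.

Object-wise colocalization: nuclear outlines segmented from the DAPI
channel are transferred onto two marker channels (e.g. an NFκB factor and
an antimicrobial-peptide reporter), each nucleus' **accumulated** (summed)
intensity is taken per channel, and Pearson correlation plus an ordinary
least-squares fit are computed on the log10-transformed sums, per gland
compartment and pooled.

Nuclei with a non-positive sum in either channel are excluded before the
log transform (log undefined); the exclusion count is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .nuclei import NucleusRecord, accumulate_intensity  # noqa: F401  (re-export)

__all__ = ["CorrelationResult", "accumulate_intensity", "correlate_channels"]


@dataclass
class CorrelationResult:
    compartment: str
    n: int
    pearson_r: float | None
    slope: float | None
    intercept: float | None
    n_excluded: int
    table: pd.DataFrame  # label, log10_a, log10_b

    @property
    def missing(self) -> bool:
        return self.pearson_r is None


def correlate_channels(
    sums_a: np.ndarray,
    sums_b: np.ndarray,
    compartments: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> dict[str, CorrelationResult]:
    """Pearson r and OLS fit of log10 per-nucleus sums, per compartment.

    Returns a mapping with one entry per compartment plus ``"pooled"``.
    Compartments (or the pool) with fewer than 3 usable nuclei are flagged
    missing (``pearson_r`` is None).
    """
    a = np.asarray(sums_a, dtype=float)
    b = np.asarray(sums_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channel sums must be paired (same length)")
    n = len(a)
    comp = (
        np.asarray(compartments)
        if compartments is not None
        else np.full(n, "all", dtype=object)
    )
    lab = np.asarray(labels) if labels is not None else np.arange(1, n + 1)

    results: dict[str, CorrelationResult] = {}
    groups = [("pooled", np.ones(n, dtype=bool))]
    groups += [(str(c), comp == c) for c in pd.unique(comp)]
    for name, sel in groups:
        aa, bb, ll = a[sel], b[sel], lab[sel]
        usable = (aa > 0) & (bb > 0)
        n_excl = int((~usable).sum())
        la, lb = np.log10(aa[usable]), np.log10(bb[usable])
        table = pd.DataFrame({"label": ll[usable], "log10_a": la, "log10_b": lb})
        if usable.sum() < 3:
            results[name] = CorrelationResult(
                compartment=name, n=int(usable.sum()), pearson_r=None,
                slope=None, intercept=None, n_excluded=n_excl, table=table,
            )
            continue
        r = float(sps.pearsonr(la, lb).statistic)
        fit = sps.linregress(la, lb)
        results[name] = CorrelationResult(
            compartment=name,
            n=int(usable.sum()),
            pearson_r=r,
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            n_excluded=n_excl,
            table=table,
        )
    return results
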