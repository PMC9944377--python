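"""Variance decomposition and cross-modal Pearson correlations.

Two statistics summarise the 92-ROI tables.  The variance decomposition
contrasts anatomical contrast with replicate noise: the SD *across
regions* (mean over samples of the SD of that sample's 92 ROI values)
against the SD *across samples* (mean over ROIs of the SD of that ROI's
value across samples).  A tract with reproducible regional structure has
the first well above the second.  Cross-modal agreement is measured by
the Pearson correlation of two modalities' 92-ROI vectors, with
multi-sample modalities averaged across samples first; p-values come from
the exact t transform ``t = r sqrt((n-2)/(1-r^2))`` with n-2 degrees of
freedom (a seeded permutation alternative is available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import DataError
from .sampling import RoiSampleTable

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class VarianceDecomposition:
    """Across-region vs across-sample SD for one modality.

    Both SDs use the unbiased (n-1) estimator.  ``units`` records the
    scale of the underlying table (raw modality units or 1-7).
    """

    modality: str
    sd_across_regions: float
    sd_across_samples: float
    n_samples: int
    n_rois: int
    units: str


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of one modality pair over the ROI vectors."""

    modality_a: str
    modality_b: str
    r: float
    r_squared: float
    p_two_sided: float
    n: int


def variance_decomposition(
    table: RoiSampleTable, modality: str
) -> VarianceDecomposition:
    """Decompose one modality's ROI table into regional vs sample SD.

    Requires at least 2 samples and at least 2 ROIs.
    """
    m = table.matrix(modality)
    n_samples, n_rois = m.shape
    if n_samples < 2:
        raise DataError(
            f"modality {modality!r} has {n_samples} sample(s); the across-sample "
            "SD needs at least 2"
        )
    if n_rois < 2:
        raise DataError(f"modality {modality!r} has {n_rois} ROI(s); need at least 2")
    return VarianceDecomposition(
        modality=modality,
        sd_across_regions=float(np.mean(np.std(m, axis=1, ddof=1))),
        sd_across_samples=float(np.mean(np.std(m, axis=0, ddof=1))),
        n_samples=n_samples,
        n_rois=n_rois,
        units=table.units_state,
    )


def pearson(
    x: np.ndarray,
    y: np.ndarray,
    names: tuple[str, str] = ("x", "y"),
    method: str = "exact",
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> CorrelationResult:
    """Product-moment correlation with a two-sided p-value.

    NaNs are removed pairwise (with a logged warning) and ``n`` reports
    the pairs actually used.  ``method='exact'`` uses the t transform with
    n-2 degrees of freedom; ``method='permutation'`` shuffles y
    ``n_permutations`` times with the given seed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError(f"need two equal-length 1-D vectors, got {x.shape}, {y.shape}")
    keep = ~(np.isnan(x) | np.isnan(y))
    if not keep.all():
        log.warning(
            "dropping %d of %d ROI pairs with missing values for %s vs %s",
            (~keep).sum(), keep.size, names[0], names[1],
        )
        x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise DataError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError(
            f"correlation undefined: constant input ({names[0]} vs {names[1]})"
        )
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    if method == "exact":
        p = float(res.pvalue)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        xc = x - x.mean()
        yc = y - y.mean()
        denom = np.sqrt((xc @ xc) * (yc @ yc))
        obs = abs(xc @ yc / denom)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(yc)
            hits += abs(xc @ perm / denom) >= obs - 1e-15
        p = (hits + 1) / (n_permutations + 1)
    else:
        raise DataError(f"unknown p-value method {method!r}")
    return CorrelationResult(
        modality_a=names[0],
        modality_b=names[1],
        r=r,
        r_squared=r * r,
        p_two_sided=p,
        n=n,
    )


def correlate_all(
    table: RoiSampleTable,
    pairs: Sequence[tuple[str, str]],
    method: str = "exact",
    seed: int | None = None,
) -> list[CorrelationResult]:
    """Pearson correlation for each requested modality pair.

    Modalities with several samples are averaged across samples before
    correlating, mirroring how replicate histology sections are combined
    before comparison with MRI.
    """
    results = []
    for a, b in pairs:
        for name in (a, b):
            if name not in table.modalities:
                raise DataError(
                    f"modality {name!r} not in table; available: {table.modalities}"
                )
        results.append(
            pearson(
                table.vector(a), table.vector(b), names=(a, b),
                method=method, seed=seed,
            )
        )
    return results
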