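"""Matching lipid-trajectory clusters to gene-trajectory clusters.

Both omics layers are clustered independently (see :mod:`lipidyn.gpmix`) and
each cluster's predicted mean curve is evaluated on the shared grid of 15
integer stage codes.  Every (lipid cluster, gene cluster) pair is then scored
by Spearman correlation of the two mean curves; Benjamini–Hochberg adjustment
runs across all pairs, and a pair *passes* when its correlation is positive
and its q-value falls below the FDR threshold (default 0.01).  A passing pair
is a *match* when both curves additionally receive the same temporal
trajectory label — early (declining from the embryonic start), late (rising
to the final postnatal stage), or peak-at-birth (maximum around code 10,
lower at both ends).  Identical labels are the operational surrogate for
"highly similar trajectory"; no quantitative second criterion is defined by
the matching procedure itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .correlate import spearman
from .dynamics import benjamini_hochberg
from .gpmix import TrajectoryCurve

__all__ = [
    "InterOmicsMatch",
    "match_interomics_clusters",
    "label_trajectory",
    "matches_to_frame",
]

TRAJECTORY_LABELS = ("early", "late", "peak_at_birth", "other")


@dataclass(frozen=True)
class InterOmicsMatch:
    lipid_cluster: int
    gene_cluster: int
    spearman_rho: float
    p_value: float
    q_value: float
    passes: bool  # positive rho and q below the FDR threshold
    lipid_label: str
    gene_label: str

    @property
    def same_trajectory(self) -> bool:
        return self.lipid_label == self.gene_label and self.lipid_label != "other"

    @property
    def is_match(self) -> bool:
        return self.passes and self.same_trajectory

    @property
    def trajectory(self) -> str:
        return self.lipid_label if self.same_trajectory else "other"


def label_trajectory(
    curve: TrajectoryCurve,
    birth_code: int = 10,
    early_window: tuple[int, int] = (1, 3),
    birth_window: tuple[int, int] = (9, 11),
    late_window: tuple[int, int] = (13, 15),
) -> str:
    """Classify a mean curve as early / late / peak_at_birth / other.

    early: maximum within the earliest codes and a negative overall
    rank-trend; late: maximum within the last codes and a positive trend;
    peak_at_birth: maximum around the birth code with lower values at both
    ends.  Windows are configurable; defaults assume the 1..15 code grid.
    """
    t = np.asarray(curve.time_codes, dtype=float)
    y = np.asarray(curve.mean, dtype=float)
    peak_code = t[int(np.argmax(y))]
    trend_rho, _ = spearman(y, t)
    if early_window[0] <= peak_code <= early_window[1] and trend_rho < 0:
        return "early"
    if late_window[0] <= peak_code <= late_window[1] and trend_rho > 0:
        return "late"
    if (
        birth_window[0] <= peak_code <= birth_window[1]
        and y[0] < y.max()
        and y[-1] < y.max()
    ):
        return "peak_at_birth"
    return "other"


def match_interomics_clusters(
    lipid_curves: Sequence[TrajectoryCurve],
    gene_curves: Sequence[TrajectoryCurve],
    fdr: float = 0.01,
    birth_code: int = 10,
) -> list[InterOmicsMatch]:
    """Score every (lipid cluster, gene cluster) pair on their mean curves.

    Both curve sets must be evaluated on the same query grid.  Returns the
    full pair table; ``passes`` marks positive correlations below the BH FDR,
    ``is_match`` additionally requires identical trajectory labels.
    """
    if not lipid_curves or not gene_curves:
        return []
    grid = np.asarray(lipid_curves[0].time_codes, dtype=float)
    for c in list(lipid_curves) + list(gene_curves):
        if not np.array_equal(np.asarray(c.time_codes, dtype=float), grid):
            raise ValueError("curve sets are evaluated on different time grids")
    lipid_labels = {c.cluster: label_trajectory(c, birth_code) for c in lipid_curves}
    gene_labels = {c.cluster: label_trajectory(c, birth_code) for c in gene_curves}
    pairs = []
    rhos, ps = [], []
    for lc in lipid_curves:
        for gc in gene_curves:
            rho, p = spearman(lc.mean, gc.mean)
            pairs.append((lc.cluster, gc.cluster))
            rhos.append(rho)
            ps.append(p)
    qs = benjamini_hochberg(ps)
    out = []
    for (li, gi), rho, p, q in zip(pairs, rhos, ps, qs):
        out.append(
            InterOmicsMatch(
                lipid_cluster=li,
                gene_cluster=gi,
                spearman_rho=float(rho),
                p_value=float(p),
                q_value=float(q),
                passes=bool(rho > 0 and q < fdr),
                lipid_label=lipid_labels[li],
                gene_label=gene_labels[gi],
            )
        )
    return out


def matches_to_frame(matches: Sequence[InterOmicsMatch]) -> pd.DataFrame:
    """Match table as a DataFrame (one row per cluster pair)."""
    return pd.DataFrame(
        [
            {
                "lipid_cluster": m.lipid_cluster,
                "gene_cluster": m.gene_cluster,
                "rho": m.spearman_rho,
                "p": m.p_value,
                "q": m.q_value,
                "passes": m.passes,
                "label": m.trajectory,
                "is_match": m.is_match,
            }
            for m in matches
        ]
    )
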