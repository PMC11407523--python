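"""Spearman correlation analyses.

Two analyses from the time-course lipidome are covered:

* stage-wise lipid–lipid correlations across selected classes (the chord-
  diagram source data): within each developmental stage's replicate samples,
  every unordered species pair among the requested classes is correlated and
  edges with p below the cutoff retained, with per-class-pair counts of
  positive and negative edges;
* cardiolipin-versus-mitochondrial-morphology correlations: each CL species'
  per-stage summary abundance against three maturation indices (crista per
  mitochondrion, mitochondria per unit cell area, crista area per
  mitochondrion area), flagging species whose retained correlations share one
  sign across all three indices.

Spearman's rho is the Pearson correlation of midranks.  The default p-value
uses the t approximation t = rho * sqrt((n-2)/(1-rho^2)) on n-2 degrees of
freedom; with the 3–4 replicates per stage typical of this design an exact
rank-permutation test can never reach p < 0.05 (the minimum two-sided exact p
is 2/n!), so the asymptotic test is the default and the exact enumeration
(n <= 9) is provided for transparency.  The raw p < 0.05 edge cutoff is used
without multiplicity correction, so edge counts are anti-conservative by
construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .nomenclature import ClassRegistry, default_registry, parse_lipid_name
from .quantify import AbundanceMatrix

__all__ = [
    "CorrelationEdge",
    "MorphologyIndices",
    "spearman",
    "stagewise_class_correlations",
    "chord_summary",
    "correlate_with_morphology",
]

MORPHOLOGY_INDEX_NAMES = ("crista_num", "mito_number", "crista_area_per_mito_area")


@dataclass(frozen=True)
class CorrelationEdge:
    feature_a: str
    feature_b: str
    stage: str  # stage label or "pooled"
    rho: float
    p_value: float

    def __post_init__(self) -> None:
        if self.feature_a == self.feature_b:
            raise ValueError("self-correlation edges are excluded")

    @property
    def sign(self) -> str:
        return "positive" if self.rho >= 0 else "negative"


@dataclass(frozen=True)
class MorphologyIndices:
    """Mitochondrial maturation indices for one developmental stage."""

    stage: str
    crista_num: float
    mito_number: float
    crista_area_per_mito_area: float

    def __post_init__(self) -> None:
        for name in MORPHOLOGY_INDEX_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def spearman(
    x: Sequence[float], y: Sequence[float], p_mode: str = "t"
) -> tuple[float, float]:
    """Spearman rank correlation with a choice of p-value computation.

    ``p_mode="t"`` (default): t approximation on n-2 degrees of freedom.
    ``p_mode="exact"``: two-sided rank-permutation enumeration, n <= 9 only.
    Constant inputs yield ``(nan, nan)`` with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("inputs differ in length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman correlation undefined")
        return np.nan, np.nan
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if p_mode == "t":
        if abs(rho) >= 1.0:
            return float(np.sign(rho)), 0.0
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
        return rho, float(min(p, 1.0))
    if p_mode == "exact":
        if n > 9:
            raise ValueError("exact enumeration supported for n <= 9 only")
        perms = np.array(list(permutations(ry)))
        rx_c = rx - rx.mean()
        p_c = perms - perms.mean(axis=1, keepdims=True)
        rhos = (p_c @ rx_c) / np.sqrt((p_c**2).sum(axis=1) * (rx_c**2).sum())
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return rho, p
    raise ValueError(f"unknown p_mode {p_mode!r}")


def stagewise_class_correlations(
    matrix: AbundanceMatrix,
    stages: Sequence[str] | None = None,
    class_set: Sequence[str] = ("CL", "PC", "PE"),
    alpha: float = 0.05,
    p_mode: str = "t",
    registry: ClassRegistry | None = None,
) -> list[CorrelationEdge]:
    """All significant pairwise species correlations within each stage.

    Within each requested stage's replicate samples (>= 3 required; smaller
    stages are skipped with a warning), every unordered pair of species
    belonging to ``class_set`` is correlated; only edges with p < ``alpha``
    are retained.
    """
    registry = registry or default_registry()
    labels = np.array(matrix.stage_labels)
    if stages is None:
        stages = sorted(set(labels), key=lambda s: matrix.stage_codes[labels == s][0])
    cls = {f: parse_lipid_name(f, registry).lipid_class for f in matrix.features}
    members = [f for f in matrix.features if cls[f] in set(class_set)]
    edges: list[CorrelationEdge] = []
    for stage in stages:
        cols = labels == stage
        if cols.sum() < 3:
            warnings.warn(f"stage {stage}: fewer than 3 samples, skipped")
            continue
        block = matrix.values.loc[members, cols]
        for a, b in combinations(members, 2):
            xa = block.loc[a].to_numpy()
            xb = block.loc[b].to_numpy()
            ok = np.isfinite(xa) & np.isfinite(xb)
            if ok.sum() < 3 or np.ptp(xa[ok]) == 0 or np.ptp(xb[ok]) == 0:
                continue
            rho, p = spearman(xa[ok], xb[ok], p_mode=p_mode)
            if p < alpha:
                edges.append(CorrelationEdge(a, b, stage, rho, p))
    return edges


def chord_summary(
    edges: Sequence[CorrelationEdge], registry: ClassRegistry | None = None
) -> pd.DataFrame:
    """Per-stage, per-class-pair counts of positive and negative edges.

    This is the underlying table of a chord diagram: band width = edge count,
    color = correlation direction.
    """
    registry = registry or default_registry()
    rows = []
    for e in edges:
        ca = parse_lipid_name(e.feature_a, registry).lipid_class
        cb = parse_lipid_name(e.feature_b, registry).lipid_class
        pair = "-".join(sorted((ca, cb)))
        rows.append({"stage": e.stage, "class_pair": pair, "sign": e.sign})
    if not rows:
        return pd.DataFrame(columns=["stage", "class_pair", "n_positive", "n_negative"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["stage", "class_pair", "sign"]).size().unstack("sign", fill_value=0)
    )
    out = out.rename(columns={"positive": "n_positive", "negative": "n_negative"})
    for c in ("n_positive", "n_negative"):
        if c not in out.columns:
            out[c] = 0
    return out[["n_positive", "n_negative"]].reset_index()


def correlate_with_morphology(
    cl_abundances: pd.DataFrame,
    indices: Sequence[MorphologyIndices],
    alpha: float = 0.05,
    p_mode: str = "t",
) -> pd.DataFrame:
    """Correlate each CL species' per-stage abundance with maturation indices.

    ``cl_abundances``: species x stage summary values (e.g. stage means),
    columns are stage labels aligned with ``indices`` (>= 4 stages).
    Returns one row per species with rho/p per index (retained where
    p < ``alpha``, else NaN) and a ``consistent`` flag set when all three
    correlations are retained with a single shared sign.
    """
    idx_stages = [m.stage for m in indices]
    if list(cl_abundances.columns) != idx_stages:
        raise ValueError(
            f"stage columns {list(cl_abundances.columns)} do not align with "
            f"morphology stages {idx_stages}"
        )
    if len(idx_stages) < 4:
        raise ValueError("need >= 4 aligned stages")
    rows = []
    for sp in cl_abundances.index:
        vals = cl_abundances.loc[sp].to_numpy(dtype=float)
        row: dict = {"species": sp}
        signs = []
        for name in MORPHOLOGY_INDEX_NAMES:
            iv = np.array([getattr(m, name) for m in indices], dtype=float)
            if np.ptp(vals) == 0 or np.ptp(iv) == 0:
                rho, p = np.nan, np.nan
            else:
                rho, p = spearman(vals, iv, p_mode=p_mode)
            keep = np.isfinite(p) and p < alpha
            row[f"rho_{name}"] = rho if keep else np.nan
            row[f"p_{name}"] = p
            signs.append(np.sign(rho) if keep else np.nan)
        row["consistent"] = (
            all(np.isfinite(s) for s in signs) and len({int(s) for s in signs}) == 1
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("species")
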