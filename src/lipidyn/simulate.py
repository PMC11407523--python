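"""Synthetic multi-stage lipidome and transcriptome generation with ground truth.

The generator emulates the study design every downstream stage expects:

* seven sampled lipidome stages (E10.5, E14.5, E17.5, P0, P1, P7, P21) with
  replicate counts 5, 5, 5, 4, 4, 3, 3 on the shared 1–15 stage-code axis;
* trajectory archetypes — early (declining from the embryonic start), late
  (rising to P21), pre-birth peak, birth peak, and null (flat) — realized as
  smooth base shapes plus a damped GP draw under the cluster-mean kernel;
* per-feature deviations drawn from the deviation kernel (Matern-5/2
  variance 0.7, lengthscale 2, plus white variance 0.1) and i.i.d. replicate
  noise, exactly the generative process the GP mixture fits;
* lipid names drawn from the shorthand grammar across a configurable class
  mix, and an internal-standard peak-area structure (one standard per class,
  unit IS areas) constructed so that quantification followed by MFP
  normalization recovers the generator's intended MFP matrix to rounding
  error;
* a transcriptome on the denser all-15-code grid whose planted gene clusters
  shadow chosen lipid archetypes through a rank-preserving monotone
  distortion, alongside decoy clusters built not to correlate positively with
  any archetype.

Everything is deterministic given (config, seed); the generator never calls
analysis code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gpmix import (
    Matern52Kernel,
    build_covariance,
    default_deviation_kernel,
    default_mean_kernel,
)
from .quantify import (
    DEFAULT_REPLICATES,
    STAGE_CODES,
    AbundanceMatrix,
    SampleMeta,
    Units,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ARCHETYPES",
    "simulate_trajectory_library",
    "simulate_lipidome",
    "simulate_transcriptome",
    "archetype_base_shape",
]

ARCHETYPES = ("early", "late", "prebirth_peak", "birth_peak", "null")

_CODES = np.arange(1.0, 16.0)

# Classes used for generated lipid names: (class, carbon range, db range, style)
_DEFAULT_CLASS_MIX: tuple[str, ...] = (
    "PC", "PE", "PS", "PI", "PG", "CL", "LPC", "SM", "Cer", "GM3",
    "TAG", "DAG", "FFA", "Cho",
)

_IS_CONCENTRATION = 0.1  # umol/ml, one internal standard per class
_RESUSPENSION_VOLUME = 0.5  # ml


@dataclass
class SimulationConfig:
    """Design of a synthetic study.

    ``features_per_archetype`` maps archetype to the number of lipid features
    planted with that trajectory; the default desk-scale design keeps the
    study's archetype variety (two large declining/rising groups, two peak
    groups, a null background) at roughly a quarter of the real lipidome's
    size so the full pipeline runs in seconds.
    """

    seed: int = 0
    replicates: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_REPLICATES)
    )
    features_per_archetype: Mapping[str, int] = field(
        default_factory=lambda: {
            "early": 30, "late": 30, "prebirth_peak": 20, "birth_peak": 20,
            "null": 110,
        }
    )
    amplitude: float = 2.5  # archetype shape amplitude on the z/log scale
    mean_curve_jitter: float = 0.3  # damping of the K_f draw added to base shapes
    deviation_scale: float = 1.0  # scaling of the per-feature K_y draw (0 = none)
    noise_sd: float = 0.3  # i.i.d. replicate noise on the z scale
    # maps the z-scale signal onto log10 micromoles; 0.25 gives individual
    # dynamic lipids ~4-10x swings across development, so the abundant stable
    # pool keeps the total polar denominator nearly constant, as observed for
    # total phospholipid in developing membranes
    log_abundance_scale: float = 0.25
    class_mix: Sequence[str] = _DEFAULT_CLASS_MIX
    gene_replicates: int = 2
    genes_per_cluster: int = 50

    def __post_init__(self) -> None:
        if any(v < 1 for v in self.replicates.values()):
            raise ValueError("replicate counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        unknown = set(self.features_per_archetype) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Planted truth for one simulated dataset."""

    features: pd.DataFrame  # index feature; columns archetype, cluster
    curves: pd.DataFrame  # cluster x code true mean curves (z scale)
    intended_mfp: pd.DataFrame | None = None  # lipidome only
    pairings: dict[int, int] = field(default_factory=dict)  # lipid->gene cluster

    def archetype_of(self, feature: str) -> str:
        return str(self.features.loc[feature, "archetype"])


def archetype_base_shape(archetype: str, codes: np.ndarray = _CODES) -> np.ndarray:
    """Deterministic base shape of an archetype on the code grid (unit scale)."""
    t = np.asarray(codes, dtype=float)
    if archetype == "early":
        y = np.exp(-(t - 1.0) / 4.0)
    elif archetype == "late":
        y = np.exp(-(15.0 - t) / 4.0)
    elif archetype == "prebirth_peak":
        y = np.exp(-((t - 8.5) ** 2) / (2 * 2.5**2))
    elif archetype == "birth_peak":
        y = np.exp(-((t - 10.0) ** 2) / (2 * 2.5**2))
    elif archetype == "null":
        return np.zeros_like(t)
    else:
        raise ValueError(f"unknown archetype {archetype!r}")
    return (y - y.mean()) / y.std()


def _argmax_ok(archetype: str, curve: np.ndarray, codes: np.ndarray) -> bool:
    peak = codes[int(np.argmax(curve))]
    if archetype == "early":
        return peak == codes[0]
    if archetype == "late":
        return peak == codes[-1]
    if archetype == "prebirth_peak":
        return 8.0 <= peak <= 9.0
    if archetype == "birth_peak":
        return peak == 10.0
    return True


def simulate_trajectory_library(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GroundTruth:
    """One true mean curve per requested archetype on codes 1..15.

    Each non-null curve is the archetype base shape (scaled to
    ``config.amplitude``) plus a damped draw from the cluster-mean kernel;
    draws that would displace the archetype's peak are rejected and redrawn,
    so peak positions always match their definitions.  Null curves are
    exactly flat (zero).  Deterministic given the config seed.
    """
    rng = rng or np.random.default_rng(config.seed)
    K_f = build_covariance(_CODES, default_mean_kernel())
    L = np.linalg.cholesky(K_f + 1e-10 * np.eye(len(_CODES)))
    curves = {}
    names = [a for a in ARCHETYPES if a in config.features_per_archetype]
    for j, arch in enumerate(names):
        base = config.amplitude * archetype_base_shape(arch)
        if arch == "null":
            curves[j + 1] = base
            continue
        for _ in range(200):
            draw = config.mean_curve_jitter * (L @ rng.standard_normal(len(_CODES)))
            cand = base + draw
            if _argmax_ok(arch, cand, _CODES):
                curves[j + 1] = cand
                break
        else:  # pragma: no cover - jitter small relative to amplitude
            curves[j + 1] = base
    feat = pd.DataFrame(
        {"archetype": names, "cluster": list(curves)},
    ).set_index(pd.Index(names, name="archetype_name"))
    curve_df = pd.DataFrame(curves).T
    curve_df.columns = _CODES.astype(int)
    curve_df.index.name = "cluster"
    return GroundTruth(features=feat, curves=curve_df)


def _lipid_name(cls: str, rng: np.random.Generator) -> str:
    """Draw one shorthand name from the grammar for a class."""
    if cls == "Cho":
        return "Cho"
    if cls == "FFA":
        c = int(rng.integers(14, 25))
        d = int(rng.integers(0, min(7, c // 3)))
        return f"FFA {c}:{d}"
    if cls == "LPC":
        c = int(rng.integers(16, 23))
        d = int(rng.integers(0, 5))
        return f"LPC{c}:{d}"
    if cls == "CL":
        c = int(2 * rng.integers(34, 41))  # 68..80, even
        d = int(rng.integers(4, 13))
        a_c = int(rng.choice([16, 18, 20]))
        a_d = int(rng.integers(1, 5))
        return f"CL{c}:{d}({a_c}:{a_d})"
    if cls in ("SM", "Cer", "GM3"):
        n_c = int(rng.integers(14, 27))  # N-acyl 14..26
        n_d = int(rng.integers(0, 3))
        return f"{cls} d18:1/{n_c}:{n_d}"
    if cls == "TAG":
        c = int(2 * rng.integers(24, 30))  # 48..58
        d = int(rng.integers(0, 7))
        a_c = int(rng.choice([16, 18]))
        a_d = int(rng.integers(0, min(2, d) + 1))
        return f"TAG{c}:{d}({a_c}:{a_d})"
    if cls == "DAG":
        c1 = int(2 * rng.integers(7, 10))
        c2 = int(2 * rng.integers(7, 10))
        d1 = int(rng.integers(0, 3))
        d2 = int(rng.integers(0, 3))
        return f"DAG{c1 + c2}:{d1 + d2}({c1}:{d1}/{c2}:{d2})"
    # diacyl glycerophospholipids
    c = int(2 * rng.integers(15, 21))  # 30..40, even
    d = int(rng.integers(0, 7))
    return f"{cls}{c}:{d}"


def _sample_design(replicates: Mapping[str, int]) -> list[SampleMeta]:
    metas = []
    for stage in sorted(replicates, key=lambda s: STAGE_CODES[s]):
        for r in range(1, replicates[stage] + 1):
            metas.append(SampleMeta(f"{stage}_r{r}", stage, r))
    return metas


def _draw_feature_signals(
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
    codes: np.ndarray,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-feature latent curves (truth + K_y deviation) on ``codes``."""
    K_y = build_covariance(codes, default_deviation_kernel())
    L = np.linalg.cholesky(K_y + 1e-10 * np.eye(len(codes)))
    rows, meta = [], []
    arch_clusters = dict(
        zip(truth.features["archetype"], truth.features["cluster"])
    )
    col_idx = [list(truth.curves.columns).index(int(c)) for c in codes]
    for arch, n in config.features_per_archetype.items():
        cluster = arch_clusters[arch]
        base = truth.curves.loc[cluster].to_numpy()[col_idx]
        for i in range(n):
            # the deviation kernel models departure from a cluster mean; null
            # background features belong to no cluster and get none, so they
            # are genuinely non-dynamic (flat truth + replicate noise only)
            if arch == "null":
                rows.append(base.copy())
            else:
                dev = config.deviation_scale * (L @ rng.standard_normal(len(codes)))
                rows.append(base + dev)
            meta.append({"archetype": arch, "cluster": cluster})
    sig = pd.DataFrame(rows)
    sig.columns = codes.astype(int)
    return sig, pd.DataFrame(meta)


def simulate_lipidome(
    config: SimulationConfig | None = None,
) -> tuple[pd.DataFrame, AbundanceMatrix, GroundTruth]:
    """Generate a lipidome study: peak table, umol matrix, and ground truth.

    Observed log-scale values are the planted cluster curve at each stage code
    plus a per-feature deviation GP draw and i.i.d. replicate noise; they are
    exponentiated onto a positive micromole scale and back-converted into
    peak areas against one unit-area internal standard per class, so that
    internal-standard quantification followed by MFP normalization recovers
    the generator's intended MFP matrix (stored in the ground truth) to
    floating-point rounding.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    truth = simulate_trajectory_library(config, rng)
    metas = _sample_design(config.replicates)
    stage_codes = np.array([m.stage_code for m in metas], dtype=float)
    uniq_codes = np.array(sorted({m.stage_code for m in metas}), dtype=float)

    sig, meta = _draw_feature_signals(truth, config, rng, uniq_codes)

    # lipid names across the class mix (Cho appears exactly once)
    classes = [c for c in config.class_mix if c != "Cho"]
    names: list[str] = []
    seen: set[str] = set()
    for i in range(len(sig)):
        cls = classes[i % len(classes)] if i > 0 else "Cho"
        for _ in range(500):
            nm = _lipid_name(cls, rng)
            if nm not in seen:
                break
        seen.add(nm)
        names.append(nm)
    sig.index = pd.Index(names, name="feature")
    meta.index = sig.index

    code_pos = {c: i for i, c in enumerate(uniq_codes)}
    # Baselines: stable (null) features are the abundant structural pool and
    # dominate the polar denominator, keeping total polar lipid roughly
    # constant across stages as in real membranes; dynamic species sit 1-2
    # orders of magnitude lower.
    is_null = (meta["archetype"] == "null").to_numpy()
    base_log = np.where(
        is_null,
        rng.normal(0.0, 0.3, size=len(sig)),
        rng.normal(-2.0, 0.5, size=len(sig)),
    )
    vals = np.empty((len(sig), len(metas)))
    S = sig.to_numpy()
    for s_i, m in enumerate(metas):
        z = S[:, code_pos[float(m.stage_code)]]
        z = z + rng.normal(0.0, config.noise_sd, size=len(sig))
        vals[:, s_i] = 10.0 ** (base_log + config.log_abundance_scale * z)

    amounts = pd.DataFrame(
        vals, index=sig.index, columns=[m.sample_id for m in metas]
    )
    matrix = AbundanceMatrix(amounts, tuple(metas), Units.umol)

    # intended MFP by the generator's own arithmetic
    from .nomenclature import default_registry, parse_lipid_name  # local: no cycle

    registry = default_registry()
    polar = np.array(
        [parse_lipid_name(f, registry).is_polar for f in amounts.index]
    )
    intended = amounts.div(amounts.loc[polar].sum(axis=0), axis=1)

    # peak table: one unit-area internal standard per class
    cls_of = {f: parse_lipid_name(f, registry).lipid_class for f in amounts.index}
    rows = []
    for f in amounts.index:
        std = f"IS-{cls_of[f]}"
        for m in metas:
            amount = amounts.loc[f, m.sample_id]
            rows.append(
                {
                    "sample_id": m.sample_id,
                    "analyte": f,
                    "peak_area": amount / (_IS_CONCENTRATION * _RESUSPENSION_VOLUME),
                    "internal_standard": std,
                    "is_concentration_umol_per_ml": _IS_CONCENTRATION,
                    "is_peak_area": 1.0,
                    "resuspension_volume_ml": _RESUSPENSION_VOLUME,
                    "stage_label": m.stage_label,
                    "replicate_index": m.replicate_index,
                }
            )
    peak_table = pd.DataFrame(rows)

    truth = GroundTruth(
        features=meta,
        curves=truth.curves,
        intended_mfp=intended,
    )
    return peak_table, matrix, truth


# decoy gene-cluster shapes chosen so none is rank-positively-correlated with
# any planted archetype: a symmetric mid-development trough (orthogonal to
# monotone shapes, anti-correlated with the peaks) and two oscillation phases
def _decoy_shapes() -> dict[str, np.ndarray]:
    t = _CODES
    u = -np.exp(-((t - 8.0) ** 2) / (2 * 3.0**2))
    s1 = np.sin(2 * np.pi * t / 5.0)
    s2 = np.cos(2 * np.pi * t / 5.0)
    out = {}
    for name, y in [("mid_trough", u), ("osc_sin", s1), ("osc_cos", s2)]:
        out[name] = (y - y.mean()) / y.std()
    return out


def simulate_transcriptome(
    config: SimulationConfig | None = None,
    planted_pairings: Sequence[str] = ("early", "late", "birth_peak"),
    n_decoys: int = 3,
) -> tuple[AbundanceMatrix, GroundTruth]:
    """Generate a transcriptome on the dense 15-code grid with planted pairings.

    Gene clusters listed in ``planted_pairings`` share the named lipid
    archetype's truth curve through a rank-preserving monotone distortion
    (``y -> y + 0.3 y^3`` after scaling), so the paired true curves have
    Spearman rho = 1 by construction.  ``n_decoys`` additional clusters use
    deterministic shapes built not to correlate positively with any
    archetype.  Replicates default to 2 per stage.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed + 1)
    lipid_truth = simulate_trajectory_library(
        config, np.random.default_rng(config.seed)
    )
    unknown = [a for a in planted_pairings if a not in lipid_truth.features.index]
    if unknown:
        raise ValueError(f"pairings reference unknown lipid archetypes: {unknown}")

    curves: dict[int, np.ndarray] = {}
    labels: list[str] = []
    pairings: dict[int, int] = {}
    for arch in planted_pairings:
        lip_cluster = int(lipid_truth.features.loc[arch, "cluster"])
        c = lipid_truth.curves.loc[lip_cluster].to_numpy()
        z = c / max(np.abs(c).max(), 1e-12)
        gid = len(curves) + 1
        curves[gid] = config.amplitude * (z + 0.3 * z**3)
        labels.append(f"paired_{arch}")
        pairings[lip_cluster] = gid
    for name, shape in list(_decoy_shapes().items())[:n_decoys]:
        gid = len(curves) + 1
        curves[gid] = config.amplitude * shape
        labels.append(f"decoy_{name}")

    reps = config.gene_replicates
    metas = _sample_design({lab: reps for lab in STAGE_CODES})
    codes = np.array([m.stage_code for m in metas], dtype=float)

    K_y = build_covariance(_CODES, default_deviation_kernel())
    L = np.linalg.cholesky(K_y + 1e-10 * np.eye(len(_CODES)))
    rows, feat_rows, names = [], [], []
    for gid, label in zip(curves, labels):
        for i in range(config.genes_per_cluster):
            dev = config.deviation_scale * (L @ rng.standard_normal(len(_CODES)))
            latent = curves[gid] + dev
            obs = latent[(codes - 1).astype(int)] + rng.normal(
                0.0, config.noise_sd, size=len(codes)
            )
            nm = f"gene_{label}_{i + 1}"
            names.append(nm)
            rows.append(obs)
            feat_rows.append({"archetype": label, "cluster": gid})
    values = pd.DataFrame(
        rows, index=pd.Index(names, name="feature"),
        columns=[m.sample_id for m in metas],
    )
    matrix = AbundanceMatrix(values, tuple(metas), Units.log)
    curve_df = pd.DataFrame(curves).T
    curve_df.columns = _CODES.astype(int)
    curve_df.index.name = "cluster"
    truth = GroundTruth(
        features=pd.DataFrame(feat_rows, index=values.index),
        curves=curve_df,
        pairings=pairings,
    )
    return matrix, truth
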