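"""File readers/writers and run manifests.

Tables are UTF-8 TSV by default (CSV accepted on read via delimiter
sniffing); missing values are encoded as "NA".  Abundance matrices travel as
a wide table (feature-name first column, sample ids in the header) with a
sidecar sample-metadata table (sample_id, stage_label, replicate_index).
Every pipeline output directory receives exactly one JSON run manifest
recording the command, config snapshot, input digests, seed, package version
and timestamps.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .gpmix import TrajectoryCurve
from .quantify import STAGE_CODES, AbundanceMatrix, SampleMeta, Units

__all__ = [
    "read_abundance_matrix",
    "write_abundance_matrix",
    "read_peak_table",
    "write_trajectory_curves",
    "read_trajectory_curves",
    "read_gene_panel",
    "RunManifest",
]

NA = "NA"


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_abundance_matrix(
    path: str | Path,
    metadata_path: str | Path,
    units: str = "umol",
) -> AbundanceMatrix:
    """Read a wide abundance table plus its sample-metadata sidecar.

    Every sample column must appear in the metadata; stage labels are
    validated against the 15-stage vocabulary; duplicate feature names are an
    error naming the offenders.
    """
    path, metadata_path = Path(path), Path(metadata_path)
    sep = _sniff_sep(path)
    wide = pd.read_csv(path, sep=sep, index_col=0, na_values=[NA])
    dup = wide.index[wide.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate feature names: {dup}")
    meta = pd.read_csv(metadata_path, sep=_sniff_sep(metadata_path))
    required = {"sample_id", "stage_label"}
    if missing := required - set(meta.columns):
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    meta = meta.set_index("sample_id")
    unmatched = [c for c in wide.columns if c not in meta.index]
    if unmatched:
        raise ValueError(f"samples without metadata: {unmatched}")
    bad = [
        (s, meta.loc[s, "stage_label"])
        for s in wide.columns
        if meta.loc[s, "stage_label"] not in STAGE_CODES
    ]
    if bad:
        raise ValueError(f"unknown stage labels: {bad}")
    metas = tuple(
        SampleMeta(
            s,
            meta.loc[s, "stage_label"],
            int(meta.loc[s].get("replicate_index", 1)),
        )
        for s in wide.columns
    )
    return AbundanceMatrix(wide, metas, Units(units))


def write_abundance_matrix(
    matrix: AbundanceMatrix, path: str | Path, metadata_path: str | Path
) -> None:
    out = matrix.values.copy()
    out.index.name = "feature"
    out.to_csv(path, sep="\t", na_rep=NA)
    meta = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in matrix.samples],
            "stage_label": [m.stage_label for m in matrix.samples],
            "replicate_index": [m.replicate_index for m in matrix.samples],
        }
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


def read_peak_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_sniff_sep(path), na_values=[NA])


def write_trajectory_curves(
    curves: Sequence[TrajectoryCurve], path: str | Path
) -> None:
    pd.concat([c.to_frame() for c in curves]).to_csv(
        path, sep="\t", index=False, na_rep=NA
    )


def read_trajectory_curves(path: str | Path) -> list[TrajectoryCurve]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    out = []
    for cl, block in df.groupby("cluster", sort=True):
        block = block.sort_values("time_code")
        out.append(
            TrajectoryCurve(
                cluster=int(cl),
                time_codes=block["time_code"].to_numpy(float),
                mean=block["mean"].to_numpy(float),
                lower=block["lower"].to_numpy(float),
                upper=block["upper"].to_numpy(float),
            )
        )
    return out


def read_gene_panel(path: str | Path) -> list[str]:
    """One-gene-per-line text file (curated panel); blank lines ignored."""
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip()]


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to every pipeline output."""

    command: str
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # path -> sha256
    outputs: list = field(default_factory=list)
    seed: int | None = None
    version: str = __version__
    python: str = platform.python_version()
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = file_digest(path)

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir) / "manifest.json"
        with open(out, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
        return out
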