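"""Lipid shorthand nomenclature: parsing, validation, formatting, classification.

Lipid species are written in the compact ``Class C:DB`` shorthand used in
targeted lipidomics, optionally carrying an acyl-chain decomposition, e.g.
``PC32:0``, ``CL76:12(16:1)``, ``DAG36:3(18:2/18:1)``, ``SM d18:1/12:0`` or
``PE36:1p(18:0p/18:1)``.  Parsing resolves the lipid class against a CSV class
registry (phospholipid / sphingolipid / neutral categories, expected chain
counts, aliases), validates acyl-sum consistency for fully annotated species,
and produces a canonical string form that round-trips.

Acyl chains are additionally classified by carbon number — short (C < 16),
long (C16–C21), very long (C ≥ 22) — and by unsaturation — saturated (0 double
bonds), mono/di-unsaturated (1–2), polyunsaturated (≥ 3).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "AcylChain",
    "LipidSpecies",
    "ClassRegistry",
    "ClassInfo",
    "AnnotationLevel",
    "ChainLength",
    "Unsaturation",
    "LipidParseError",
    "LipidValidationError",
    "parse_lipid_name",
    "classify_chain_length",
    "classify_unsaturation",
    "acyl_composition_profile",
]


class LipidParseError(ValueError):
    """Raised when a shorthand name cannot be parsed."""


class LipidValidationError(ValueError):
    """Raised when a parsed name violates a structural invariant."""


class AnnotationLevel(str, Enum):
    class_only = "class_only"
    sum_composition = "sum_composition"
    partial_acyl = "partial_acyl"
    full_acyl = "full_acyl"


class ChainLength(str, Enum):
    short = "short"
    long = "long"
    very_long = "very_long"


class Unsaturation(str, Enum):
    saturated = "saturated"
    mono_di = "mono_di"
    poly = "poly"


@dataclass(frozen=True)
class AcylChain:
    """A single fatty-acyl (or long-chain-base) constituent."""

    carbons: int
    double_bonds: int
    ether: bool = False  # plasmanyl/plasmenyl linkage, written with a "p" suffix
    sphingoid: str = ""  # "", "d" (dihydroxy) or "t" (trihydroxy) base prefix

    def __post_init__(self) -> None:
        if self.carbons < 1:
            raise LipidValidationError(f"acyl carbons must be >= 1, got {self.carbons}")
        if self.double_bonds < 0:
            raise LipidValidationError(
                f"acyl double bonds must be >= 0, got {self.double_bonds}"
            )
        if self.double_bonds > self.carbons:
            raise LipidValidationError(
                f"acyl {self.carbons}:{self.double_bonds} has more double bonds than carbons"
            )
        if self.sphingoid not in ("", "d", "t"):
            raise LipidValidationError(f"unknown sphingoid prefix {self.sphingoid!r}")

    def __str__(self) -> str:
        return f"{self.sphingoid}{self.carbons}:{self.double_bonds}{'p' if self.ether else ''}"


@dataclass(frozen=True)
class ClassInfo:
    code: str
    category: str  # "pl", "spl" or "neutral"
    n_chains: int
    aliases: tuple[str, ...] = ()

    @property
    def polar(self) -> bool:
        return self.category in ("pl", "spl")


class ClassRegistry:
    """Registry of lipid class codes, their polar category and chain counts.

    Backed by a CSV (``class_code, category, n_chains, aliases``) so new
    classes can be added without code changes.
    """

    def __init__(self, infos: Iterable[ClassInfo]):
        self._infos: dict[str, ClassInfo] = {}
        self._alias: dict[str, str] = {}
        for info in infos:
            self._infos[info.code] = info
            self._alias[info.code] = info.code
            for a in info.aliases:
                self._alias[a] = info.code
        # longest-first token list for greedy prefix matching during parsing
        self._tokens = sorted(self._alias, key=len, reverse=True)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ClassRegistry":
        infos = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                aliases = tuple(a for a in (row.get("aliases") or "").split(";") if a)
                infos.append(
                    ClassInfo(
                        code=row["class_code"].strip(),
                        category=row["category"].strip(),
                        n_chains=int(row["n_chains"]),
                        aliases=aliases,
                    )
                )
        return cls(infos)

    @classmethod
    def default(cls) -> "ClassRegistry":
        with resources.as_file(
            resources.files("lipidyn.data") / "class_registry.csv"
        ) as p:
            return cls.from_csv(p)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["class_code", "category", "n_chains", "aliases"])
            for info in self._infos.values():
                w.writerow([info.code, info.category, info.n_chains, ";".join(info.aliases)])

    def resolve(self, code: str) -> ClassInfo:
        try:
            return self._infos[self._alias[code]]
        except KeyError:
            raise LipidParseError(f"unregistered lipid class {code!r}") from None

    def __contains__(self, code: str) -> bool:
        return code in self._alias

    def match_prefix(self, s: str) -> tuple[ClassInfo, str] | None:
        """Greedy longest-alias match at the start of ``s``.

        Returns the matched class and the remainder of the string, or None.
        The token must be followed by a non-letter (digit, space, "(" or end
        of string) — or by a sphingoid chain like ``d18:1`` — so that ``PC``
        never swallows the ``P`` of another code.
        """
        for tok in self._tokens:
            if s.startswith(tok):
                rest = s[len(tok):].lstrip()
                if not rest or not rest[0].isalpha() or _looks_like_chain(rest):
                    return self.resolve(tok), rest
        return None


_DEFAULT_REGISTRY: ClassRegistry | None = None


def default_registry() -> ClassRegistry:
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = ClassRegistry.default()
    return _DEFAULT_REGISTRY


@dataclass(frozen=True)
class LipidSpecies:
    """A parsed lipid species with class, sum composition and acyl annotation."""

    lipid_class: str
    total_carbons: int
    total_double_bonds: int
    acyls: tuple[AcylChain, ...] = ()
    annotation_level: AnnotationLevel = AnnotationLevel.sum_composition
    ether: bool = False
    is_polar: bool = False
    label: str = ""  # isotope-label tag on standards, e.g. "d5"
    raw: str = field(default="", compare=False)

    def __str__(self) -> str:
        return self.canonical()

    def canonical(self) -> str:
        """Canonical shorthand: no space between class code and composition."""
        pre = f"{self.label}-" if self.label else ""
        if self.annotation_level is AnnotationLevel.class_only:
            return pre + self.lipid_class
        s = f"{pre}{self.lipid_class}{self.total_carbons}:{self.total_double_bonds}"
        if self.ether:
            s += "p"
        if self.acyls:
            s += "(" + "/".join(str(a) for a in self.acyls) + ")"
        return s


_LABEL_RE = re.compile(r"^d(\d+)-(?=[A-Za-z])")
_ACYL_RE = re.compile(r"^([dt]?)(\d+):(\d+)(p?)$")
_SUM_RE = re.compile(r"^(\d+):(\d+)(p?)$")


def _parse_acyl(token: str, name: str) -> AcylChain:
    m = _ACYL_RE.match(token.strip())
    if not m:
        raise LipidParseError(f"cannot parse acyl token {token!r} in {name!r}")
    sph, c, db, eth = m.groups()
    try:
        return AcylChain(int(c), int(db), ether=bool(eth), sphingoid=sph)
    except LipidValidationError as e:
        raise LipidValidationError(f"{name!r}: {e}") from None


def parse_lipid_name(name: str, registry: ClassRegistry | None = None) -> LipidSpecies:
    """Parse a shorthand lipid name into a :class:`LipidSpecies`.

    Accepts optional whitespace between the class code and composition
    (``"TAG 54:2(18:2)"`` and ``"PC32:0"`` alike), isotope-label prefixes on
    standards (``d5-``, ``d9-`` ... stored as a label tag), ether ``p``
    suffixes, and three composition forms: sum only (``PC32:0``), sum with an
    acyl list (``CL76:12(16:1)``), and a bare chain list (``SM d18:1/12:0``,
    ``BMP 14:0/14:0``) whose totals are computed from the chains.

    Raises :class:`LipidParseError` for unparseable names or unregistered
    classes, and :class:`LipidValidationError` when a complete acyl list
    disagrees with the declared totals.
    """
    registry = registry or default_registry()
    if not name or not name.strip():
        raise LipidParseError("empty lipid name")
    s = name.strip()

    label = ""
    m = _LABEL_RE.match(s)
    if m:
        # "d18:1..." is a sphingoid chain, not a label; the lookahead above
        # already requires a letter after the dash so "d5-CL..." matches here.
        label = f"d{m.group(1)}"
        s = s[m.end():]

    matched = registry.match_prefix(s)
    if matched is None:
        raise LipidParseError(f"unregistered or unrecognized lipid class in {name!r}")
    info, rest = matched

    if not rest:
        return LipidSpecies(
            lipid_class=info.code,
            total_carbons=0,
            total_double_bonds=0,
            annotation_level=AnnotationLevel.class_only,
            is_polar=info.polar,
            label=label,
            raw=name,
        )

    acyls: tuple[AcylChain, ...] = ()
    ether = False

    # form: sum composition with optional parenthesised acyl list
    paren = rest.find("(")
    head = rest[:paren].strip() if paren >= 0 else rest
    m = _SUM_RE.match(head)
    if m and paren >= 0:
        if not rest.endswith(")"):
            raise LipidParseError(f"unbalanced parentheses in {name!r}")
        inner = rest[paren + 1 : -1]
        acyls = tuple(_parse_acyl(t, name) for t in inner.split("/"))
        tc, tdb, eth = int(m.group(1)), int(m.group(2)), bool(m.group(3))
        ether = eth or any(a.ether for a in acyls)
        level = _acyl_level(info, acyls, tc, tdb, name)
        return LipidSpecies(
            info.code, tc, tdb, acyls, level, ether, info.polar, label, name
        )
    if m:
        tc, tdb, eth = int(m.group(1)), int(m.group(2)), bool(m.group(3))
        if info.n_chains == 1:
            # single-chain class: the sum IS the one acyl
            acyls = (AcylChain(tc, tdb, ether=eth),)
            level = AnnotationLevel.full_acyl
        else:
            level = AnnotationLevel.sum_composition
        return LipidSpecies(
            info.code, tc, tdb, acyls, level, eth, info.polar, label, name
        )

    # form: bare chain list, e.g. "d18:1/12:0" or "14:0/14:0" or "d17:1"
    tokens = rest.split("/")
    acyls = tuple(_parse_acyl(t, name) for t in tokens)
    tc = sum(a.carbons for a in acyls)
    tdb = sum(a.double_bonds for a in acyls)
    ether = any(a.ether for a in acyls)
    level = (
        AnnotationLevel.full_acyl
        if info.n_chains in (0, len(acyls))
        else AnnotationLevel.partial_acyl
    )
    return LipidSpecies(info.code, tc, tdb, acyls, level, ether, info.polar, label, name)


def _looks_like_chain(s: str) -> bool:
    return bool(re.match(r"^[dt]\d+:\d+", s.strip()))


def _acyl_level(
    info: ClassInfo, acyls: tuple[AcylChain, ...], tc: int, tdb: int, name: str
) -> AnnotationLevel:
    sc = sum(a.carbons for a in acyls)
    sdb = sum(a.double_bonds for a in acyls)
    complete = len(acyls) >= info.n_chains or (sc == tc and sdb == tdb)
    if complete:
        if sc != tc or sdb != tdb:
            raise LipidValidationError(
                f"{name!r}: full acyl list {sc}:{sdb} does not match declared totals {tc}:{tdb}"
            )
        return AnnotationLevel.full_acyl
    if sc > tc or sdb > tdb:
        raise LipidValidationError(
            f"{name!r}: annotated acyls {sc}:{sdb} exceed declared totals {tc}:{tdb}"
        )
    return AnnotationLevel.partial_acyl


def classify_chain_length(carbons: int) -> ChainLength:
    """Chain-length category: short (C<16), long (C16–21), very long (C>=22)."""
    if carbons < 1:
        raise ValueError(f"carbons must be >= 1, got {carbons}")
    if carbons < 16:
        return ChainLength.short
    if carbons <= 21:
        return ChainLength.long
    return ChainLength.very_long


def classify_unsaturation(double_bonds: int) -> Unsaturation:
    """Unsaturation category: saturated (0), mono/di (1–2), poly (>=3)."""
    if double_bonds < 0:
        raise ValueError(f"double bonds must be >= 0, got {double_bonds}")
    if double_bonds == 0:
        return Unsaturation.saturated
    if double_bonds <= 2:
        return Unsaturation.mono_di
    return Unsaturation.poly


def acyl_composition_profile(
    species_list: Sequence[LipidSpecies],
    abundances: Sequence[float],
    mode: str = "by_acyl",
) -> pd.DataFrame:
    """Per-class abundance profile over (chain-length x unsaturation) categories.

    Parameters
    ----------
    species_list, abundances
        Aligned species and their abundances for a single stage.
    mode
        ``"by_acyl"``: each annotated acyl receives an equal share of the
        species abundance; species with no annotated acyls are skipped.
        ``"by_totals"``: the species' total carbons/double bonds are
        classified as one unit carrying the full abundance.

    Returns a DataFrame indexed by lipid class with a 9-column MultiIndex
    (chain-length category, unsaturation category); rows sum to the class
    total abundance of the species that contributed.
    """
    if len(species_list) != len(abundances):
        raise ValueError(
            f"species ({len(species_list)}) and abundances ({len(abundances)}) differ in length"
        )
    if mode not in ("by_acyl", "by_totals"):
        raise ValueError(f"unknown mode {mode!r}")
    cols = pd.MultiIndex.from_product(
        [[c.value for c in ChainLength], [u.value for u in Unsaturation]],
        names=["chain_length", "unsaturation"],
    )
    if not species_list:
        return pd.DataFrame(columns=cols, dtype=float)
    classes = sorted({sp.lipid_class for sp in species_list})
    out = pd.DataFrame(0.0, index=classes, columns=cols)
    for sp, ab in zip(species_list, abundances):
        if mode == "by_totals":
            if sp.annotation_level is AnnotationLevel.class_only:
                continue
            key = (
                classify_chain_length(sp.total_carbons).value,
                classify_unsaturation(sp.total_double_bonds).value,
            )
            out.loc[sp.lipid_class, key] += ab
        else:
            if not sp.acyls:
                continue
            share = ab / len(sp.acyls)
            for a in sp.acyls:
                key = (
                    classify_chain_length(a.carbons).value,
                    classify_unsaturation(a.double_bonds).value,
                )
                out.loc[sp.lipid_class, key] += share
    return out
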