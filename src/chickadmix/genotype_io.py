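"""Genotype matrices, metadata tables, and site-level filtering.

Genotypes are held as an individuals × loci matrix of reference-allele
counts (0, 1, 2) with :data:`MISSING` (−1) as the sentinel for no-calls.
VCF input goes through :mod:`cyvcf2`; only the diploid GT subfield is used.
Coordinates are 1-based VCF positions throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

#: Sentinel for a missing diploid call (``./.`` or any half-call).
MISSING: int = -1

#: Documented metadata header, in order.
METADATA_COLUMNS = (
    "band",
    "species",
    "sex",
    "age",
    "sympatry",
    "elevation",
    "latitude",
    "year",
    "bander",
    "mass",
    "tarsus",
)

_SEX_ALIASES = {"M": "M", "F": "F", "U": "unknown", "UNKNOWN": "unknown"}
_AGE_ALIASES = {"HY": "HY", "AHY": "AHY_ASY", "ASY": "AHY_ASY", "AHY_ASY": "AHY_ASY"}
_SPECIES_LEVELS = {"A", "B"}
_SYMPATRY_LEVELS = {"sympatric", "allopatric"}


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed into a genotype matrix."""


@dataclass
class GenotypeMatrix:
    """Diploid genotypes for a cohort.

    Attributes
    ----------
    individuals : list of str
        Sample identifiers, in column order of the source VCF.
    loci : list of (str, int)
        ``(chrom, pos)`` keys, positions 1-based, unique and ordered.
    calls : ndarray of shape (n_individuals, n_loci)
        Reference-allele counts in {0, 1, 2} or :data:`MISSING`.
    site_qual : ndarray of shape (n_loci,)
        Phred-scaled site quality (NaN when absent).
    site_depth : ndarray or None
        Per-locus mean depth, when the source records it.
    """

    individuals: list[str]
    loci: list[tuple[str, int]]
    calls: np.ndarray
    site_qual: np.ndarray
    site_depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.site_qual = np.asarray(self.site_qual, dtype=float)
        if self.calls.shape != (len(self.individuals), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls must be in {0, 1, 2, MISSING}")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("locus keys must be unique")
        if self.site_depth is not None:
            self.site_depth = np.asarray(self.site_depth, dtype=float)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def individual_index(self, band: str) -> int:
        return self.individuals.index(band)

    def subset_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a matrix restricted to loci where ``keep`` is True (order kept)."""
        keep = np.asarray(keep, dtype=bool)
        return GenotypeMatrix(
            individuals=list(self.individuals),
            loci=[l for l, k in zip(self.loci, keep) if k],
            calls=self.calls[:, keep],
            site_qual=self.site_qual[keep],
            site_depth=None if self.site_depth is None else self.site_depth[keep],
        )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF (v4.2, GT first in FORMAT) into a :class:`GenotypeMatrix`.

    ``./.`` and half-calls become :data:`MISSING`; phased separators are
    accepted. Multi-allelic sites are skipped with a warning. Mean site
    depth is taken from an ``MDP`` INFO field when present.
    """
    path = Path(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 raises various types
        raise VcfParseError(f"{path}: cannot open as VCF: {exc}") from exc
    individuals = list(vcf.samples)
    loci: list[tuple[str, int]] = []
    quals: list[float] = []
    depths: list[float] = []
    any_depth = False
    columns: list[np.ndarray] = []
    line_no = 0
    try:
        for rec in vcf:
            line_no += 1
            if len(rec.ALT) != 1:
                warnings.warn(
                    f"{path}: skipping multi-allelic site {rec.CHROM}:{rec.POS}",
                    stacklevel=2,
                )
                continue
            gts = rec.genotypes
            if len(gts) != len(individuals):
                raise VcfParseError(
                    f"{path}: record {line_no} ({rec.CHROM}:{rec.POS}) has "
                    f"{len(gts)} genotypes for {len(individuals)} samples"
                )
            col = np.empty(len(individuals), dtype=np.int8)
            for i, g in enumerate(gts):
                a, b = g[0], g[1] if len(g) > 2 else -1
                if a < 0 or b < 0:
                    col[i] = MISSING
                else:
                    # reference-allele count: allele code 0 is REF
                    col[i] = int(a == 0) + int(b == 0)
            loci.append((rec.CHROM, rec.POS))
            quals.append(float(rec.QUAL) if rec.QUAL is not None else np.nan)
            mdp = rec.INFO.get("MDP")
            if mdp is not None:
                any_depth = True
                depths.append(float(mdp))
            else:
                depths.append(np.nan)
            columns.append(col)
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(f"{path}: parse error at record {line_no + 1}: {exc}") from exc
    calls = (
        np.column_stack(columns)
        if columns
        else np.empty((len(individuals), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        individuals=individuals,
        loci=loci,
        calls=calls,
        site_qual=np.asarray(quals),
        site_depth=np.asarray(depths) if any_depth else None,
    )


_GT_STRINGS = {2: "0/0", 1: "0/1", 0: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 with GT-only FORMAT.

    REF/ALT are placeholder A/G alleles; mean depth, when present, is
    stored in an ``MDP`` INFO field so a write→read round trip is exact.
    """
    path = Path(path)
    chroms = list(dict.fromkeys(c for c, _ in matrix.loci))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=chickadmix\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            '##INFO=<ID=MDP,Number=1,Type=Float,Description="Mean per-sample depth">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.individuals)
            + "\n"
        )
        for j, (chrom, pos) in enumerate(matrix.loci):
            qual = matrix.site_qual[j]
            qual_s = "." if np.isnan(qual) else f"{qual:g}"
            if matrix.site_depth is not None and not np.isnan(matrix.site_depth[j]):
                info = f"MDP={matrix.site_depth[j]:g}"
            else:
                info = "."
            gts = "\t".join(_GT_STRINGS[int(g)] for g in matrix.calls[:, j])
            fh.write(
                f"{chrom}\t{pos}\tsnp{j + 1}\tA\tG\t{qual_s}\tPASS\t{info}\tGT\t{gts}\n"
            )


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-individual metadata CSV into a typed table.

    Expected columns: ``band, species, sex, age, sympatry, elevation,
    latitude, year, bander, mass, tarsus``. ``sex`` accepts ``U`` as an
    alias for ``unknown``; ``AHY`` and ``ASY`` collapse to ``AHY_ASY``.
    Rows with missing mass/tarsus or out-of-vocabulary categories are
    rejected with the offending row named.
    """
    df = pd.read_csv(path, dtype={"band": str, "bander": str})
    missing_cols = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing metadata columns {missing_cols}")

    for idx, row in df.iterrows():
        if pd.isna(row["mass"]) or pd.isna(row["tarsus"]):
            raise ValueError(f"{path}: row {idx}: missing mass or tarsus")
        if not row["mass"] > 0 or not row["tarsus"] > 0:
            raise ValueError(f"{path}: row {idx}: non-positive mass or tarsus")

    def _map(col: str, mapping: dict[str, str] | None, levels: set[str]) -> pd.Series:
        vals = df[col].astype(str).str.strip()
        if mapping is not None:
            vals = vals.str.upper().map(lambda v: mapping.get(v, v))
        bad = ~vals.isin(levels)
        if bad.any():
            idx = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: row {idx}: invalid {col} value {df[col].iloc[idx]!r}"
            )
        return vals

    df["sex"] = _map("sex", _SEX_ALIASES, {"M", "F", "unknown"})
    df["age"] = _map("age", _AGE_ALIASES, {"HY", "AHY_ASY"})
    df["species"] = _map("species", None, _SPECIES_LEVELS)
    df["sympatry"] = _map("sympatry", None, _SYMPATRY_LEVELS)
    for col in ("elevation", "latitude", "mass", "tarsus"):
        df[col] = df[col].astype(float)
    df["year"] = df["year"].astype(int)
    return df


def site_statistics(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus MAF (from non-missing calls) and missingness fraction."""
    calls = matrix.calls
    nonmiss = calls != MISSING
    n_nonmiss = nonmiss.sum(axis=0)
    ref_count = np.where(nonmiss, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = ref_count / (2.0 * n_nonmiss)
    maf = np.minimum(p, 1.0 - p)
    missingness = 1.0 - n_nonmiss / matrix.n_individuals
    return pd.DataFrame(
        {
            "chrom": [c for c, _ in matrix.loci],
            "pos": [p_ for _, p_ in matrix.loci],
            "qual": matrix.site_qual,
            "maf": maf,
            "missingness": missingness,
            "mean_depth": (
                matrix.site_depth
                if matrix.site_depth is not None
                else np.full(matrix.n_loci, np.nan)
            ),
        }
    )


def filter_sites(
    matrix: GenotypeMatrix,
    min_qual: float = 30.0,
    min_maf: float = 0.0001,
    max_missing: float = 0.5,
    depth_bounds: tuple[float, float] | None = None,
) -> GenotypeMatrix:
    """Apply site-level quality filters, preserving locus order.

    A locus is retained when QUAL ≥ ``min_qual`` (so "below 30" is removed
    and exactly 30 kept), MAF ≥ ``min_maf`` computed from non-missing
    calls, missingness ≤ ``max_missing``, and — when depth is recorded and
    bounds given — mean depth within ``depth_bounds`` inclusive. The
    default ``min_maf`` reads the 0.01% threshold as a proportion
    (0.0001); pass 0.01 for a 1% rule. An empty result is returned (with a
    warning), not raised.
    """
    for name, v in (
        ("min_qual", min_qual),
        ("min_maf", min_maf),
        ("max_missing", max_missing),
    ):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite")
    stats = site_statistics(matrix)
    keep = (
        (stats["qual"].to_numpy() >= min_qual)
        & (stats["maf"].to_numpy() >= min_maf)
        & (stats["missingness"].to_numpy() <= max_missing)
    )
    if depth_bounds is not None and matrix.site_depth is not None:
        lo, hi = depth_bounds
        d = matrix.site_depth
        keep &= np.isnan(d) | ((d >= lo) & (d <= hi))
    if not keep.any():
        warnings.warn("no loci pass the site filters; returning empty matrix", stacklevel=2)
    return matrix.subset_loci(keep)


def filter_report(
    matrix: GenotypeMatrix,
    min_qual: float = 30.0,
    min_maf: float = 0.0001,
    max_missing: float = 0.5,
    depth_bounds: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Per-locus criterion values and a ``pass`` flag, mirroring :func:`filter_sites`."""
    stats = site_statistics(matrix)
    stats["pass_qual"] = stats["qual"] >= min_qual
    stats["pass_maf"] = stats["maf"] >= min_maf
    stats["pass_missing"] = stats["missingness"] <= max_missing
    if depth_bounds is not None and matrix.site_depth is not None:
        lo, hi = depth_bounds
        stats["pass_depth"] = stats["mean_depth"].isna() | stats["mean_depth"].between(lo, hi)
    else:
        stats["pass_depth"] = True
    stats["pass"] = (
        stats["pass_qual"] & stats["pass_maf"] & stats["pass_missing"] & stats["pass_depth"]
    )
    return stats
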