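"""Synthetic two-species admixture datasets with mass–tarsus allometry.

Generates the data structure the downstream pipeline assumes, without any
field data: two parental populations diverged at ~10⁴ biallelic loci with
a tail of highly differentiated (near-diagnostic) sites, admixed
individuals of defined ancestry classes (F1, first-generation backcrosses),
and per-individual morphometrics in which body mass scales allometrically
with tarsus length and can carry a configurable multiplicative condition
deficit in sympatry and/or for hybrids.

Genotypes are simulated under the same independence model the hybrid-index
likelihood assumes (unlinked loci, Hardy–Weinberg within ancestry class):
for true index h, each allele copy at locus l is the reference allele with
probability (1 − h)·p_A,l + h·p_B,l. Background parental frequencies
follow a Balding–Nichols scheme (ancestral frequency uniform on
[0.05, 0.95], each parental frequency Beta-drifted with parameter
``divergence_f``); a ``diagnostic_fraction`` of loci are instead drawn
near-fixed for alternative alleles. Hybrid classes are labelled with
species-A plumage in the metadata, mirroring field identification of
cryptic hybrids.

Everything is deterministic given ``seed``; mass is recorded to 0.5 g and
tarsus to 0.01 mm, as on a banding sheet.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from chickadmix.genotype_io import MISSING, GenotypeMatrix, write_vcf

#: True hybrid index by ancestry class.
H_TRUE = {"pureA": 0.0, "BC1A": 0.25, "F1": 0.5, "BC1B": 0.75, "pureB": 1.0}

#: Which species' morphometrics an ancestry class expresses (hybrids look like A).
_PLUMAGE = {"pureA": "A", "BC1A": "A", "F1": "A", "BC1B": "A", "pureB": "B"}

_BANDERS = ("KG", "KO", "TB", "ST", "JF")


def _default_allometry() -> dict:
    # intercepts chosen so mean mass lands near 11.37 g (A) / 11.59 g (B)
    # at the species' mean tarsus under the default slopes
    return {
        "A": {
            "ln_a": math.log(11.37) - 1.09 * math.log(17.83),
            "b": 1.09,
            "resid_sd": 0.04,
        },
        "B": {
            "ln_a": math.log(11.59) - 1.12 * math.log(18.62),
            "b": 1.12,
            "resid_sd": 0.04,
        },
    }


def _default_tarsus() -> dict:
    return {"A": {"mean": 17.83, "sd": 0.5}, "B": {"mean": 18.62, "sd": 0.5}}


def _default_covariates() -> dict:
    # sympatry happens in mid-elevation transitional habitat
    return {
        "sympatric": {"elevation": (1800.0, 2600.0), "latitude": (35.0, 52.0)},
        "allopatric": {"elevation": (1200.0, 3200.0), "latitude": (35.0, 55.0)},
    }


def _default_class_counts() -> dict:
    return {"pureA": 100, "pureB": 100, "F1": 5, "BC1A": 10, "BC1B": 5}


def _default_sympatry() -> dict:
    return {"pureA": 0.75, "pureB": 0.75, "F1": 1.0, "BC1A": 1.0, "BC1B": 1.0}


@dataclass
class SimulationDesign:
    """Full parameterisation of one synthetic dataset.

    Defaults give a cohort of 220 birds (170 sympatric, 20 of them
    hybrids), 10⁴ loci with a 3% near-diagnostic tail, species mean tarsi
    of 17.83/18.62 mm, mean masses near 11.4/11.6 g, and a 5% sympatric
    condition deficit applied multiplicatively to mass.
    """

    n_loci: int = 10_000
    divergence_f: float = 0.15
    diagnostic_fraction: float = 0.03
    class_counts: dict = field(default_factory=_default_class_counts)
    sympatry_assignment: dict = field(default_factory=_default_sympatry)
    condition_deficit_sympatry: float = 0.05
    condition_deficit_hybrid: float = 0.05
    allometry_params: dict = field(default_factory=_default_allometry)
    tarsus_params: dict = field(default_factory=_default_tarsus)
    covariate_params: dict = field(default_factory=_default_covariates)
    mass_increment: float = 0.5
    tarsus_increment: float = 0.01
    unknown_sex_fraction: float = 0.3
    missing_rate: float = 0.0
    site_qual: float = 60.0
    year_range: tuple = (2005, 2016)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not (np.isfinite(self.divergence_f) and 0.0 < self.divergence_f < 1.0):
            raise ValueError("divergence_f must be in (0, 1)")
        if not (
            np.isfinite(self.diagnostic_fraction)
            and 0.0 <= self.diagnostic_fraction <= 1.0
        ):
            raise ValueError("diagnostic_fraction must be in [0, 1]")
        unknown = set(self.class_counts) - set(H_TRUE)
        if unknown:
            raise ValueError(f"unknown ancestry classes {sorted(unknown)}")
        if any(c < 0 for c in self.class_counts.values()):
            raise ValueError("class counts must be >= 0")
        for name, d in (
            ("condition_deficit_sympatry", self.condition_deficit_sympatry),
            ("condition_deficit_hybrid", self.condition_deficit_hybrid),
        ):
            if not (np.isfinite(d) and 0.0 <= d < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


def simulate_parental_frequencies(
    n_loci: int,
    divergence_f: float,
    diagnostic_fraction: float,
    seed: int,
) -> pd.DataFrame:
    """Draw per-locus parental reference-allele frequencies.

    Background loci: ancestral frequency π ~ U(0.05, 0.95), then each
    parental frequency ~ Beta(π(1−f)/f, (1−π)(1−f)/f) independently — the
    Balding–Nichols drift model with divergence parameter f. A
    ``diagnostic_fraction`` of loci (positions chosen at random) are
    instead near-fixed for opposite alleles: p_A ~ U(0.95, 1), p_B ~
    U(0, 0.05).

    Returns a frame with columns ``chrom, pos, p_a, p_b, is_diagnostic_truth``
    (truth flag = simulated under the near-fixed regime).
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if not (np.isfinite(divergence_f) and 0.0 < divergence_f < 1.0):
        raise ValueError("divergence_f must be in (0, 1)")
    if not (np.isfinite(diagnostic_fraction) and 0.0 <= diagnostic_fraction <= 1.0):
        raise ValueError("diagnostic_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    pi = rng.uniform(0.05, 0.95, size=n_loci)
    scale = (1.0 - divergence_f) / divergence_f
    p_a = rng.beta(pi * scale, (1.0 - pi) * scale)
    p_b = rng.beta(pi * scale, (1.0 - pi) * scale)
    n_diag = int(round(diagnostic_fraction * n_loci))
    diag_idx = rng.choice(n_loci, size=n_diag, replace=False)
    p_a[diag_idx] = rng.uniform(0.95, 1.0, size=n_diag)
    p_b[diag_idx] = rng.uniform(0.0, 0.05, size=n_diag)
    truth = np.zeros(n_loci, dtype=bool)
    truth[diag_idx] = True
    return pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, n_loci + 1),
            "p_a": p_a,
            "p_b": p_b,
            "is_diagnostic_truth": truth,
        }
    )


def _round_to(x: np.ndarray, increment: float) -> np.ndarray:
    return np.round(np.round(x / increment) * increment, 6)


def simulate_individuals(
    design: SimulationDesign, freqs: pd.DataFrame
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate genotypes and banding-sheet metadata for one cohort.

    Genotypes at locus l for an individual of true index h are
    Binomial(2, (1−h)·p_A,l + h·p_B,l) reference-allele counts, with a
    flat ``missing_rate`` of no-calls. Tarsus is Normal per species;
    ln(mass) = ln_a + b·ln(tarsus) + Σ log(1 − deficit) + Normal(0, σ)
    with the sympatry deficit applied to sympatric birds and the hybrid
    deficit to F1/BC1 classes. The metadata table carries the documented
    field columns plus simulation-truth columns ``ancestry_class`` and
    ``h_true``.
    """
    if len(freqs) != design.n_loci:
        raise ValueError(
            f"frequency table has {len(freqs)} rows for n_loci={design.n_loci}"
        )
    rng = np.random.default_rng(design.seed)
    p_a = freqs["p_a"].to_numpy()
    p_b = freqs["p_b"].to_numpy()
    n_loci = design.n_loci

    blocks: list[np.ndarray] = []
    records: list[dict] = []
    counter = 0
    for cls in ("pureA", "pureB", "F1", "BC1A", "BC1B"):
        n = int(design.class_counts.get(cls, 0))
        if n == 0:
            continue
        h = H_TRUE[cls]
        species = _PLUMAGE[cls]
        is_hybrid_class = cls in ("F1", "BC1A", "BC1B")
        phi = (1.0 - h) * p_a + h * p_b
        g = rng.binomial(2, phi, size=(n, n_loci)).astype(np.int8)
        if design.missing_rate > 0:
            g[rng.random((n, n_loci)) < design.missing_rate] = MISSING
        blocks.append(g)

        n_symp = int(round(design.sympatry_assignment.get(cls, 0.0) * n))
        sympatry = np.array(
            ["sympatric"] * n_symp + ["allopatric"] * (n - n_symp)
        )
        tp = design.tarsus_params[species]
        ap = design.allometry_params[species]
        tarsus = rng.normal(tp["mean"], tp["sd"], size=n)
        ln_mass = ap["ln_a"] + ap["b"] * np.log(tarsus)
        ln_mass += np.where(
            sympatry == "sympatric", math.log1p(-design.condition_deficit_sympatry), 0.0
        )
        if is_hybrid_class:
            ln_mass += math.log1p(-design.condition_deficit_hybrid)
        ln_mass += rng.normal(0.0, ap["resid_sd"], size=n)
        mass = _round_to(np.exp(ln_mass), design.mass_increment)
        tarsus = _round_to(tarsus, design.tarsus_increment)

        u = rng.random(n)
        sex = np.where(
            u < design.unknown_sex_fraction,
            "unknown",
            np.where(u < design.unknown_sex_fraction + (1 - design.unknown_sex_fraction) / 2, "M", "F"),
        )
        age = np.where(rng.random(n) < 0.5, "HY", "AHY_ASY")
        for i in range(n):
            cov = design.covariate_params[sympatry[i]]
            records.append(
                {
                    "band": f"SB{counter:04d}",
                    "species": species,
                    "sex": sex[i],
                    "age": age[i],
                    "sympatry": sympatry[i],
                    "elevation": float(rng.uniform(*cov["elevation"])),
                    "latitude": float(rng.uniform(*cov["latitude"])),
                    "year": int(rng.integers(design.year_range[0], design.year_range[1] + 1)),
                    "bander": _BANDERS[int(rng.integers(len(_BANDERS)))],
                    "mass": float(mass[i]),
                    "tarsus": float(tarsus[i]),
                    "ancestry_class": cls,
                    "h_true": h,
                }
            )
            counter += 1

    if not records:
        raise ValueError("design produced zero individuals")
    calls = np.vstack(blocks)
    metadata = pd.DataFrame(records)
    matrix = GenotypeMatrix(
        individuals=list(metadata["band"]),
        loci=list(zip(freqs["chrom"].astype(str), freqs["pos"].astype(int))),
        calls=calls,
        site_qual=np.full(n_loci, float(design.site_qual)),
    )
    return matrix, metadata


def simulate_dataset(
    design: SimulationDesign,
) -> tuple[pd.DataFrame, GenotypeMatrix, pd.DataFrame]:
    """Frequencies + genotypes + metadata for one design (one seed)."""
    freqs = simulate_parental_frequencies(
        design.n_loci, design.divergence_f, design.diagnostic_fraction, design.seed
    )
    matrix, metadata = simulate_individuals(design, freqs)
    return freqs, matrix, metadata


def parental_panels(metadata: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Reference panels from the simulation truth: allopatric pure individuals.

    Mirrors the use of allopatric birds far from the contact zone as
    fixed-ancestry references (index 0 for species A, 1 for species B).
    """
    pure_a = metadata.query("ancestry_class == 'pureA' and sympatry == 'allopatric'")
    pure_b = metadata.query("ancestry_class == 'pureB' and sympatry == 'allopatric'")
    return list(pure_a["band"]), list(pure_b["band"])


def write_dataset(design: SimulationDesign, outdir: str | Path) -> dict[str, Path]:
    """Write VCF + metadata CSV + a manifest JSON recording design and seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    freqs, matrix, metadata = simulate_dataset(design)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "metadata": outdir / "metadata.csv",
        "frequencies": outdir / "true_frequencies.tsv",
        "manifest": outdir / "manifest.json",
    }
    write_vcf(matrix, paths["vcf"])
    metadata.to_csv(paths["metadata"], index=False)
    freqs.to_csv(paths["frequencies"], sep="\t", index=False)
    with open(paths["manifest"], "w") as fh:
        json.dump({"design": asdict(design)}, fh, indent=2, default=list)
    return paths
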