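"""Per-SNP differentiation between two parental panels.

Implements the Weir & Cockerham (1984) two-population θ̂ estimator from
genotype counts — the convention VCFtools uses for per-site F_ST — plus a
matrix-level scan and diagnostic-locus selection by a strict F_ST
threshold. Negative per-site estimates are retained unclamped; they simply
never pass the threshold.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from chickadmix.genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


def weir_cockerham_fst(genotypes_pop_a, genotypes_pop_b) -> float:
    """Weir–Cockerham per-site θ̂ for two populations of diploid genotypes.

    Parameters are arrays of reference-allele counts in {0, 1, 2} with
    :data:`~chickadmix.genotype_io.MISSING` entries dropped. Returns
    θ̂ = a / (a + b + c) from the among-population (a), among-individual
    (b) and within-individual (c) variance components; uses observed
    heterozygosity and supports unequal sample sizes. May be negative.
    Returns NaN when a + b + c = 0 (both panels monomorphic for the same
    allele).

    Raises
    ------
    ValueError
        If either population has no non-missing call.
    """
    ga = np.asarray(genotypes_pop_a)
    gb = np.asarray(genotypes_pop_b)
    ga = ga[ga != MISSING]
    gb = gb[gb != MISSING]
    if ga.size == 0 or gb.size == 0:
        raise ValueError("each population needs at least one non-missing genotype")

    r = 2
    n = np.array([ga.size, gb.size], dtype=float)  # diploid individuals
    p = np.array([ga.mean() / 2.0, gb.mean() / 2.0])  # ref-allele frequency
    h = np.array([(ga == 1).mean(), (gb == 1).mean()])  # observed het proportion

    # fixed difference: analytically b = c = 0, theta = 1 exactly; computing
    # the components floating-point would lose the identity to cancellation
    if {p[0], p[1]} == {0.0, 1.0}:
        return 1.0

    n_bar = n.mean()
    n_total = n.sum()
    n_c = (n_total - (n**2).sum() / n_total) / (r - 1)
    p_bar = (n * p).sum() / n_total
    s2 = (n * (p - p_bar) ** 2).sum() / ((r - 1) * n_bar)
    h_bar = (n * h).sum() / n_total

    if n_bar <= 1:
        # single individual per panel: the n̄−1 terms are undefined
        raise ValueError("Weir-Cockerham components need n > 1 in at least one panel")

    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - (r - 1) / r * s2
        - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2.0

    denom = a + b + c
    if denom == 0:
        return float("nan")
    return float(a / denom)


def fst_scan(
    matrix: GenotypeMatrix,
    panel_a: list[str],
    panel_b: list[str],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-locus F_ST scan between two disjoint panels of individuals.

    Returns a locus frequency table with columns ``chrom, pos, n_a, n_b,
    p_a, p_b, fst, diagnostic`` where ``n_a``/``n_b`` are non-missing
    allele counts, ``p_a``/``p_b`` are reference-allele frequencies with a
    Jeffreys-style ``pseudocount`` added to each allele count (keeps
    downstream hybrid-index likelihoods finite at loci fixed in a panel),
    and ``diagnostic`` is initialised False pending
    :func:`select_diagnostic_loci`.
    """
    set_a, set_b = set(panel_a), set(panel_b)
    if not set_a or not set_b:
        raise ValueError("both panels must be nonempty")
    if set_a & set_b:
        raise ValueError(f"panels overlap: {sorted(set_a & set_b)}")
    idx_a = [matrix.individual_index(s) for s in panel_a]
    idx_b = [matrix.individual_index(s) for s in panel_b]

    rows = []
    for j, (chrom, pos) in enumerate(matrix.loci):
        ga = matrix.calls[idx_a, j]
        gb = matrix.calls[idx_b, j]
        ga_v = ga[ga != MISSING]
        gb_v = gb[gb != MISSING]
        n_a, n_b = 2 * ga_v.size, 2 * gb_v.size
        theta = weir_cockerham_fst(ga, gb)
        p_a = (ga_v.sum() + pseudocount) / (n_a + 2 * pseudocount)
        p_b = (gb_v.sum() + pseudocount) / (n_b + 2 * pseudocount)
        rows.append((chrom, pos, n_a, n_b, p_a, p_b, theta, False))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "n_a", "n_b", "p_a", "p_b", "fst", "diagnostic"]
    )


def select_diagnostic_loci(table: pd.DataFrame, threshold: float = 0.65) -> pd.DataFrame:
    """Flag loci with F_ST strictly above ``threshold`` as diagnostic.

    NaN estimates are never selected. Returns a copy of the table with the
    ``diagnostic`` column set; raises if the selection is empty (the hybrid
    index cannot be estimated from zero loci — lower the threshold).
    """
    if table.empty:
        raise ValueError("locus table is empty")
    out = table.copy()
    fst = out["fst"].to_numpy()
    out["diagnostic"] = np.where(np.isnan(fst), False, fst > threshold)
    n_sel = int(out["diagnostic"].sum())
    logger.info("selected %d/%d loci with FST > %g", n_sel, len(out), threshold)
    if n_sel == 0:
        raise ValueError(
            f"no loci with FST > {threshold}; reduce the threshold to estimate "
            "hybrid indices"
        )
    return out
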