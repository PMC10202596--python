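"""Expression-evidence statistics.

Species-level TPM averaging, Mann–Whitney U group comparisons (exact or
tie-corrected normal approximation, two-sided, no continuity correction),
antioxidant-panel screens with direction-of-change summaries, kinetic-assay
unit conversion, and activity–expression correlation.

The test units are species means, not individuals — in the study's figures
each dot is a species, averaged over its sequenced individuals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: molar extinction coefficients (mM^-1 cm^-1) for the hydrolysis products of
#: the four substrates: phenyl acetate -> phenol, chlorpyrifos oxon ->
#: trichloropyridinol, diazoxon -> IMHP, paraoxon -> p-nitrophenol
DEFAULT_EXTINCTION_COEFFICIENTS: dict[str, float] = {
    "AREase": 1.31,
    "CPOase": 5.56,
    "DZOase": 3.0,
    "POase": 18.0,
}

#: pseudocount added before the natural-log TPM transform so that
#: zero-expression pseudogenes remain usable
LOG_TPM_PSEUDOCOUNT = 0.01


@dataclass(frozen=True)
class GroupTestResult:
    U: float
    Z: float
    p: float
    n1: int
    n2: int
    method: str = "exact"

    def __post_init__(self) -> None:
        if not 0 <= self.U <= self.n1 * self.n2:
            raise ValueError("U outside [0, n1*n2]")
        if not 0 <= self.p <= 1:
            raise ValueError("p outside [0, 1]")


@dataclass(frozen=True)
class CorrelationResult:
    r_squared: float
    slope: float
    intercept: float
    n: int


@dataclass(frozen=True)
class KineticAssay:
    """One kinetic measurement: absorbance change per minute plus the
    constants needed to convert it to enzyme units.

    ``epsilon`` is the molar extinction coefficient in mM^-1 cm^-1,
    ``reaction_to_sample_volume`` the ratio of total reaction volume to the
    plasma volume assayed, ``dilution`` the plasma pre-dilution factor.
    """

    delta_A_per_min: float
    epsilon: float
    path_cm: float = 1.0
    dilution: float = 1.0
    reaction_to_sample_volume: float = 1.0

    def __post_init__(self) -> None:
        if self.delta_A_per_min < 0:
            raise ValueError("delta_A_per_min must be nonnegative")
        if min(self.epsilon, self.path_cm, self.dilution, self.reaction_to_sample_volume) <= 0:
            raise ValueError("epsilon, path, dilution and volume ratio must be positive")


# ---------------------------------------------------------------------------
# species averaging


def average_by_species(table: pd.DataFrame, gene: str) -> dict[str, float]:
    """Arithmetic mean TPM per species for one gene; species without a
    measurement are omitted."""
    sub = table[table["gene"] == gene]
    if sub.empty:
        raise ValueError(f"gene {gene!r} not present in expression table")
    return sub.groupby("species", sort=True)["tpm"].mean().to_dict()


# ---------------------------------------------------------------------------
# Mann–Whitney U


def _u_and_z(a: np.ndarray, b: np.ndarray) -> tuple[float, float, bool]:
    """U statistic of the first group (midranks for ties) and the
    tie-corrected normal deviate without continuity correction."""
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    U = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    z = 0.0 if var <= 0 else (U - mu) / math.sqrt(var)
    has_ties = bool((counts > 1).any())
    return float(U), float(z), has_ties


def mann_whitney_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    mode: str = "auto",
) -> GroupTestResult:
    """Two-sided Mann–Whitney U test.

    ``mode='exact'`` enumerates the null permutation distribution of U
    (valid without ties); ``'normal'`` uses the tie-corrected normal
    approximation without continuity correction; ``'auto'`` picks exact for
    n1*n2 <= 400 tie-free samples and normal otherwise.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    U, Z, has_ties = _u_and_z(a, b)
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    use_exact = mode == "exact" or (mode == "auto" and len(a) * len(b) <= 400 and not has_ties)
    if use_exact and has_ties:
        warnings.warn("ties present; falling back to the normal approximation")
        use_exact = False
    if use_exact:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        p = float(res.pvalue)
        method = "exact"
    else:
        p = float(2.0 * stats.norm.sf(abs(Z)))
        p = min(1.0, p)
        method = "normal"
    return GroupTestResult(U=U, Z=Z, p=p, n1=len(a), n2=len(b), method=method)


# ---------------------------------------------------------------------------
# antioxidant panel


@dataclass
class PanelSummary:
    n_tested: int
    n_significant: int
    n_down: int
    n_up: int
    per_gene: pd.DataFrame


def compare_gene_panel(
    table: pd.DataFrame,
    genes: Sequence[str],
    groups: tuple[str, str],
    alpha: float = 0.05,
    correction: str | None = None,
) -> PanelSummary:
    """Per-gene two-sided Mann–Whitney tests between two clades over species
    means, with a direction-of-change summary.

    Direction is the sign of (median of group A) − (median of group B) over
    species means: ``down`` means lower in group A. No multiplicity
    correction by default; ``correction='fdr_bh'`` applies
    Benjamini–Hochberg.
    """
    if not genes:
        raise ValueError("gene panel must be nonempty")
    clade_a, clade_b = groups
    rows = []
    for gene in genes:
        sub = table[table["gene"] == gene]
        if sub.empty:
            continue
        means = sub.groupby(["clade", "species"], sort=True)["tpm"].mean()
        try:
            va = means.loc[clade_a].to_numpy()
        except KeyError:
            va = np.array([])
        try:
            vb = means.loc[clade_b].to_numpy()
        except KeyError:
            vb = np.array([])
        if len(va) == 0 or len(vb) == 0:
            continue  # gene must be measured in both groups
        if len(va) < 2 or len(vb) < 2:
            warnings.warn(f"gene {gene}: fewer than 2 species in a group; skipped")
            continue
        res = mann_whitney_test(va, vb)
        direction = "down" if np.median(va) < np.median(vb) else "up"
        rows.append(
            dict(gene=gene, U=res.U, Z=res.Z, p=res.p, n1=res.n1, n2=res.n2,
                 direction=direction)
        )
    per_gene = pd.DataFrame(rows, columns=["gene", "U", "Z", "p", "n1", "n2", "direction"])
    if correction == "fdr_bh" and len(per_gene):
        reject, p_adj, *_ = multipletests(per_gene["p"], alpha=alpha, method="fdr_bh")
        per_gene["p_adjusted"] = p_adj
        sig = per_gene[reject]
    elif correction is None:
        sig = per_gene[per_gene["p"] < alpha] if len(per_gene) else per_gene
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return PanelSummary(
        n_tested=len(per_gene),
        n_significant=len(sig),
        n_down=int((sig["direction"] == "down").sum()) if len(sig) else 0,
        n_up=int((sig["direction"] == "up").sum()) if len(sig) else 0,
        per_gene=per_gene,
    )


# ---------------------------------------------------------------------------
# kinetic assays


def activity_from_kinetics(assay: KineticAssay) -> float:
    """Enzyme activity in U/mL from a kinetic absorbance slope.

    U/mL = (ΔA/min ÷ (ε · path)) × (reaction volume / sample volume) ×
    dilution, where one unit hydrolyzes 1 µmol of substrate per minute
    (ε in mM⁻¹·cm⁻¹ makes the quotient mM/min of product, i.e. µmol/mL/min).
    """
    rate_mM_per_min = assay.delta_A_per_min / (assay.epsilon * assay.path_cm)
    return rate_mM_per_min * assay.reaction_to_sample_volume * assay.dilution


# ---------------------------------------------------------------------------
# activity vs expression


def correlate_activity_expression(
    activity: Mapping[str, float],
    expression: Mapping[str, float],
) -> CorrelationResult:
    """OLS of plasma activity on natural-log TPM (with pseudocount) across
    the species shared by both tables; reports R^2."""
    shared = sorted(set(activity) & set(expression))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared species, got {len(shared)}")
    y = np.array([activity[s] for s in shared], dtype=float)
    x = np.log(np.array([expression[s] for s in shared], dtype=float) + LOG_TPM_PSEUDOCOUNT)
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CorrelationResult(
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        slope=float(coef[1]),
        intercept=float(coef[0]),
        n=len(shared),
    )
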