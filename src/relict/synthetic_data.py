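"""Synthetic data generation with recorded ground truth.

Everything a study of recurrent gene loss consumes can be simulated here:
Yule trees, codon alignments evolved under branch-class-specific dN/dS,
injected pseudogenizing lesions, clade-shifted log-normal expression tables,
and binary functional-status traits from the two-state switching model that
the phylogenetic logistic regression assumes.

One global integer seed expands into named substreams (tree, alignment,
lesions, expression, trait) so that adding or re-running one stage never
perturbs the draws of another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import CodonAlignment
from .codon_selection import CodonModel, _ClassTM, build_codon_rate_matrix
from .genetics import CODON_AA, CODON_INDEX, SENSE_CODONS, STOP_CODONS, translate_codon
from .trees import Phylogeny

N_STATES = len(SENSE_CODONS)

_STREAMS = {"tree": 1, "alignment": 2, "lesions": 3, "expression": 4, "trait": 5}


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for a named simulation stage."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[name],)))


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Expression means are on the natural-log TPM scale; the defaults put
    terrestrial species means around 400 TPM and aquatic around 8 TPM, i.e.
    inside the observed terrestrial 73–2,251 and aquatic 0.1–62 TPM ranges.
    """

    seed: int = 0
    n_tips: int = 16
    n_codons: int = 500
    kappa: float = 2.0
    omega_by_class: dict[str, float] = field(default_factory=lambda: {"bg": 0.2})
    codon_freqs: np.ndarray | None = None
    expression_means: dict[str, float] = field(
        default_factory=lambda: {"terrestrial": math.log(400.0), "aquatic": math.log(8.0)}
    )
    expression_sd: float = 0.8
    beta: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.5]))
    alpha_signal: float = 5.0

    def __post_init__(self) -> None:
        if self.codon_freqs is None:
            self.codon_freqs = np.full(N_STATES, 1.0 / N_STATES)
        self.codon_freqs = np.asarray(self.codon_freqs, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.codon_freqs.shape != (N_STATES,):
            raise ValueError(f"codon_freqs must have length {N_STATES} (sense codons only)")
        if abs(float(self.codon_freqs.sum()) - 1.0) > 1e-12:
            raise ValueError("codon_freqs must sum to 1 within 1e-12")
        if (self.codon_freqs < 0).any():
            raise ValueError("codon_freqs must be nonnegative")
        if self.kappa <= 0 or self.expression_sd < 0 or self.alpha_signal <= 0:
            raise ValueError("rates and standard deviations must be positive")
        if any(w < 0 for w in self.omega_by_class.values()):
            raise ValueError("omega values must be nonnegative")


@dataclass(frozen=True)
class SimTruth:
    """Immutable ground truth emitted alongside simulated data."""

    true_lesions: tuple[tuple[str, str, int], ...] = ()
    true_omegas: tuple[tuple[str, float], ...] = ()
    true_beta: tuple[float, ...] = ()
    true_status: tuple[tuple[str, int], ...] = ()

    def lesion_set(self) -> set[tuple[str, str, int]]:
        return set(self.true_lesions)


# ---------------------------------------------------------------------------
# trees


def generate_yule_tree(n_tips: int, seed: int, birth_rate: float = 1.0) -> Phylogeny:
    """Pure-birth (Yule) tree: rooted, bifurcating, ultrametric, with tips
    labelled sp01..spNN. Deterministic for a fixed seed."""
    if n_tips < 2:
        raise ValueError("n_tips must be at least 2")
    rng = substream(seed, "tree")
    # lineage bookkeeping: each split ends one lineage and starts two new ones
    history: list[tuple[float, int, int]] = []
    t = 0.0
    active: list[int] = [0, 1]
    birth_time = {0: 0.0, 1: 0.0}
    next_id = 2
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        split = active[rng.integers(len(active))]
        history.append((t, split, next_id))
        birth_time[next_id] = t
        birth_time[next_id + 1] = t
        active.remove(split)
        active.extend([next_id, next_id + 1])
        next_id += 2
    t += rng.exponential(1.0 / (birth_rate * len(active)))  # time to present

    # build node arrays: lineage ids -> tree nodes
    # every lineage that split becomes an internal node; active ones are tips
    parent_of_lineage: dict[int, int] = {}
    for _, parent, first_child in history:
        parent_of_lineage[first_child] = parent
        parent_of_lineage[first_child + 1] = parent
    split_time = {parent: when for when, parent, _ in history}
    split_time[-1] = 0.0

    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    lengths = np.zeros(n_nodes)
    labels: list[str | None] = [None] * n_nodes

    # map lineages to node ids: root is the virtual ancestor of lineages 0,1
    node_of: dict[int, int] = {}
    node_of[-1] = 0  # root
    nid = 1
    all_lineages = sorted(birth_time)
    for lin in all_lineages:
        node_of[lin] = nid
        nid += 1
    for lin in all_lineages:
        v = node_of[lin]
        p = parent_of_lineage.get(lin, -1)
        parent[v] = node_of[p]
        end = split_time.get(lin, t)  # internal ends at its split, tip at present
        lengths[v] = end - birth_time[lin]
    width = max(2, len(str(n_tips)))
    tip_counter = 1
    for lin in all_lineages:
        if lin not in split_time:
            labels[node_of[lin]] = f"sp{tip_counter:0{width}d}"
            tip_counter += 1
    return Phylogeny(parent, lengths, labels)


# ---------------------------------------------------------------------------
# codon alignments


def simulate_codon_alignment(
    tree: Phylogeny, config: SimConfig, seed: int | None = None
) -> CodonAlignment:
    """Evolve an in-frame alignment along the tree under per-class GY94
    matrices (61 sense codons — no stop codon is ever introduced)."""
    rng = substream(config.seed if seed is None else seed, "alignment")
    for v in range(tree.n_nodes):
        if v != tree.root and tree.classes[v] not in config.omega_by_class:
            raise ValueError(
                f"branch class {tree.classes[v]!r} has no omega in the configuration"
            )
    model = CodonModel(
        kappa=config.kappa,
        omega_by_class=dict(config.omega_by_class),
        codon_freqs=config.codon_freqs,
    )
    tms = {
        c: _ClassTM(build_codon_rate_matrix(model, c), model.codon_freqs)
        for c in set(config.omega_by_class) & set(tree.classes)
    }
    n = config.n_codons
    states: dict[int, np.ndarray] = {}
    states[tree.root] = rng.choice(N_STATES, size=n, p=config.codon_freqs)
    for v in reversed(tree.postorder):  # preorder
        p = int(tree.parent[v])
        if p < 0:
            continue
        t = float(tree.lengths[v])
        if t <= 0:
            states[v] = states[p].copy()
            continue
        P = tms[tree.classes[v]].P(t)
        cum = np.cumsum(P, axis=1)
        cum /= cum[:, -1:]
        u = rng.random(n)
        states[v] = (cum[states[p]] < u[:, None]).sum(axis=1)
    seqs = {}
    for v, label in zip(tree.tip_indices, tree.tip_labels):
        seqs[label] = "".join(SENSE_CODONS[s] for s in states[v])
    ref = tree.tip_labels[0]
    return CodonAlignment(seqs, ref_species=ref)


LESION_KINDS = ("premature_stop", "frameshift", "critical_site_sub")


def inject_lesions(
    alignment: CodonAlignment,
    plan: Sequence[tuple[str, str, int]],
    seed: int,
) -> tuple[CodonAlignment, SimTruth]:
    """Apply planned pseudogenizing lesions and record them as ground truth.

    Plan entries are (species, kind, codon_position) with positions 1-based
    in the alignment's codon coordinates. Frameshifts delete 1 or 2
    nucleotides (never a multiple of 3) at the start of the target codon,
    leaving gap characters so the alignment shape is preserved.
    """
    rng = substream(seed, "lesions")
    seqs = {sp: list(s) for sp, s in alignment.seqs.items()}
    n_codons = alignment.n_codons
    truth: list[tuple[str, str, int]] = []
    for species, kind, pos in plan:
        if species not in seqs:
            raise KeyError(f"species {species!r} not in alignment")
        if kind not in LESION_KINDS:
            raise ValueError(f"unknown lesion kind {kind!r}")
        if not 1 <= pos <= n_codons:
            raise ValueError(f"codon position {pos} outside 1..{n_codons}")
        start = 3 * (pos - 1)
        if kind == "premature_stop":
            stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
            seqs[species][start:start + 3] = list(stop)
        elif kind == "frameshift":
            k = int(rng.integers(1, 3))  # delete 1 or 2 nt
            for i in range(k):
                seqs[species][start + i] = "-"
        else:  # critical_site_sub
            ref = alignment.ref_species or alignment.species[0]
            ref_codon = alignment.seqs[ref][start:start + 3]
            ref_aa = translate_codon(ref_codon)
            choices = [i for i, aa in enumerate(CODON_AA) if aa != ref_aa]
            new = SENSE_CODONS[choices[rng.integers(len(choices))]]
            seqs[species][start:start + 3] = list(new)
        truth.append((species, kind, pos))
    out = CodonAlignment(
        {sp: "".join(chars) for sp, chars in seqs.items()},
        ref_species=alignment.ref_species,
    )
    return out, SimTruth(true_lesions=tuple(truth))


# ---------------------------------------------------------------------------
# expression tables


def simulate_expression_table(
    species_clades: Mapping[str, str],
    config: SimConfig,
    gene: str = "Pon1",
    n_individuals: int | Mapping[str, int] = 3,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-individual TPM values drawn log-normally around clade means.

    Returns a tidy frame with columns (individual, species, clade, gene, tpm).
    """
    rng = substream(config.seed if seed is None else seed, "expression")
    rows = []
    for species, clade in species_clades.items():
        if clade not in config.expression_means:
            raise ValueError(f"clade {clade!r} has no configured expression mean")
        k = n_individuals[species] if isinstance(n_individuals, Mapping) else n_individuals
        mu = config.expression_means[clade]
        for i in range(k):
            tpm = max(0.0, float(np.exp(mu + config.expression_sd * rng.standard_normal())))
            rows.append(
                dict(individual=f"{species}_{i + 1}", species=species, clade=clade,
                     gene=gene, tpm=tpm)
            )
    return pd.DataFrame(rows, columns=["individual", "species", "clade", "gene", "tpm"])


# ---------------------------------------------------------------------------
# binary traits under the two-state switching model


def branch_equilibria(tree: Phylogeny, X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Per-node equilibrium probability of state 1.

    Each branch is assigned the logistic equilibrium of the mean covariate
    row over its descendant tips (for a tip branch, the tip's own row); the
    root uses the mean over all tips. This is the rate parameterisation
    shared by the simulator and the estimator.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != tree.n_tips:
        raise ValueError("X must have one row per tip")
    if X.shape[1] != len(beta):
        raise ValueError(f"dimension mismatch: X has {X.shape[1]} columns, beta {len(beta)}")
    tip_row = {v: i for i, v in enumerate(tree.tip_indices)}
    eta = np.zeros(tree.n_nodes)
    for v in tree.postorder:
        if not tree.children[v]:
            eta[v] = X[tip_row[v]] @ beta
        else:
            tips = tree.descendant_tips(v)
            eta[v] = X[[tip_row[t] for t in tips]].mean(axis=0) @ beta
    return 1.0 / (1.0 + np.exp(-eta))


def simulate_binary_trait(
    tree: Phylogeny,
    X: np.ndarray,
    beta: np.ndarray,
    alpha_signal: float,
    seed: int,
) -> dict[str, int]:
    """Binary tip states from a two-state switching process whose
    equilibrium P(state 1) on each branch is logistic(x_branch · beta) and
    whose total switching rate is ``alpha_signal`` (per unit branch length)."""
    if alpha_signal <= 0:
        raise ValueError("alpha_signal must be positive")
    beta = np.asarray(beta, dtype=float)
    p_eq = branch_equilibria(tree, X, beta)
    rng = substream(seed, "trait")
    state = np.zeros(tree.n_nodes, dtype=int)
    state[tree.root] = int(rng.random() < p_eq[tree.root])
    for v in reversed(tree.postorder):  # preorder
        p = int(tree.parent[v])
        if p < 0:
            continue
        decay = math.exp(-alpha_signal * float(tree.lengths[v]))
        prob1 = p_eq[v] + (state[p] - p_eq[v]) * decay
        state[v] = int(rng.random() < prob1)
    return {label: int(state[v]) for v, label in zip(tree.tip_indices, tree.tip_labels)}


# ---------------------------------------------------------------------------
# clade helpers


def pick_foreground_clade(tree: Phylogeny, target_fraction: float = 0.33) -> list[str]:
    """Choose the clade whose tip count is closest to a target fraction of
    all tips (used to designate a 'loss' / aquatic clade in simulations)."""
    best, best_tips = None, None
    n = tree.n_tips
    for v in range(tree.n_nodes):
        if v == tree.root or not tree.children[v]:
            continue
        tips = tree.descendant_tips(v)
        if len(tips) >= n - 1:
            continue
        score = abs(len(tips) / n - target_fraction)
        if best is None or score < best:
            best, best_tips = score, tips
    if best_tips is None:  # fall back to a single tip
        best_tips = [tree.tip_indices[0]]
    labels = dict(zip(tree.tip_indices, tree.tip_labels))
    return [labels[v] for v in best_tips]
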