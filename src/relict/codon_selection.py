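"""Branch-partitioned codon substitution model (GY94 family).

Implements the likelihood machinery behind branch-specific dN/dS tests:
a 61-state codon rate matrix per branch class (kappa for transitions, omega
for nonsynonymous changes, target-codon frequency pi_j), Felsenstein pruning
with per-pattern rescaling, maximum-likelihood fitting of (kappa, omegas,
branch lengths) with analytic branch-length gradients, and likelihood-ratio
tests between nested branch partitions.

Conventions
-----------
* Branch lengths are expected substitutions per codon site; each class
  matrix is rescaled so the mean substitution rate at stationarity is 1.
* Alignment columns containing a gap or ambiguity in any species are
  excluded from the likelihood; premature stop codons (pseudogene input)
  are masked as missing data for that species only, with a warning.
* The model is time-reversible, so the log-likelihood does not depend on
  root placement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .alignment import CodonAlignment
from .genetics import (
    CODON_INDEX,
    CODON_NT_INDEX,
    NONSYN_PAIR,
    SENSE_CODONS,
    SINGLE_DIFF,
    STOP_CODONS,
    TRANSITION_PAIR,
)
from .trees import Phylogeny

N_STATES = len(SENSE_CODONS)


# ---------------------------------------------------------------------------
# model / partition containers


@dataclass
class CodonModel:
    """GY94-style codon model with one omega per branch class."""

    kappa: float
    omega_by_class: dict[str, float]
    codon_freqs: np.ndarray

    def __post_init__(self) -> None:
        self.codon_freqs = np.asarray(self.codon_freqs, dtype=float)
        if self.codon_freqs.shape != (N_STATES,):
            raise ValueError(f"codon_freqs must have length {N_STATES}")
        if abs(self.codon_freqs.sum() - 1.0) > 1e-8:
            raise ValueError("codon_freqs must sum to 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if any(w < 0 for w in self.omega_by_class.values()):
            raise ValueError("omega values must be nonnegative")


#: constraint forms: "free", ("fixed", value), ("tied", other_class)
Constraint = object


@dataclass
class BranchPartition:
    """Assignment of branches to omega classes plus per-class constraints.

    ``assignment`` maps node index -> class label for the edge above that
    node; when None the tree's own branch-class tags are used. Constraints
    default to every class free.
    """

    assignment: dict[int, str] | None = None
    constraints: dict[str, Constraint] = field(default_factory=dict)

    def classes_for(self, tree: Phylogeny) -> list[str]:
        out = list(tree.classes)
        if self.assignment:
            for v, c in self.assignment.items():
                out[v] = c
        return out

    @staticmethod
    def single(label: str = "all") -> "BranchPartition":
        return BranchPartition(assignment=None, constraints={}, )._as_uniform(label)

    def _as_uniform(self, label: str) -> "BranchPartition":
        self._uniform_label = label
        return self

    def resolved_classes(self, tree: Phylogeny) -> list[str]:
        if getattr(self, "_uniform_label", None) is not None:
            return [self._uniform_label] * tree.n_nodes
        return self.classes_for(tree)

    def free_and_bound(self, used_classes: Sequence[str]) -> tuple[list[str], dict]:
        """Split used classes into free parameters and bound (fixed/tied) ones.

        Returns (free_class_list, resolver) where resolver maps every used
        class to ("free", cls) / ("fixed", value) / ("tied", root_free_class).
        """
        resolver: dict[str, tuple] = {}
        free: list[str] = []
        for c in dict.fromkeys(used_classes):
            spec = self.constraints.get(c, "free")
            if spec == "free":
                resolver[c] = ("free", c)
                free.append(c)
            elif isinstance(spec, tuple) and spec[0] == "fixed":
                resolver[c] = ("fixed", float(spec[1]))
            elif isinstance(spec, tuple) and spec[0] == "tied":
                target = spec[1]
                seen = {c}
                while True:
                    tspec = self.constraints.get(target, "free")
                    if isinstance(tspec, tuple) and tspec[0] == "tied":
                        target = tspec[1]
                        if target in seen:
                            raise ValueError("cyclic tie in partition constraints")
                        seen.add(target)
                    else:
                        break
                resolver[c] = ("tied", target)
                tspec = self.constraints.get(target, "free")
                if tspec == "free" and target not in free and target not in used_classes:
                    free.append(target)
            else:
                raise ValueError(f"bad constraint for class {c!r}: {spec!r}")
        # ensure tied targets that are free appear once
        for c, (kind, target) in list(resolver.items()):
            if kind == "tied":
                tspec = self.constraints.get(target, "free")
                if tspec == "free" and target not in free:
                    free.append(target)
        return free, resolver


@dataclass
class ModelFit:
    model: CodonModel
    branch_lengths: np.ndarray  # per node, edge above node (root entry 0)
    logL: float
    n_params: int
    converged: bool
    partition: BranchPartition
    details: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# rate matrix


def build_codon_rate_matrix(model: CodonModel, branch_class: str) -> np.ndarray:
    """61x61 generator: q_ij ∝ pi_j * kappa^[transition] * omega^[nonsyn] for
    single-nucleotide codon pairs, 0 otherwise; rows sum to 0; scaled so the
    expected rate at stationarity is 1."""
    if branch_class not in model.omega_by_class:
        raise KeyError(f"branch class {branch_class!r} has no omega in the model")
    omega = model.omega_by_class[branch_class]
    pi = model.codon_freqs
    Q = np.where(SINGLE_DIFF, np.tile(pi, (N_STATES, 1)), 0.0)
    Q *= np.where(TRANSITION_PAIR, model.kappa, 1.0)
    Q *= np.where(NONSYN_PAIR, omega, 1.0)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -float(pi @ np.diag(Q))
    if rate <= 0:
        raise ValueError("degenerate rate matrix (zero total rate)")
    return Q / rate


class _ClassTM:
    """Eigendecomposition of one class's reversible generator; produces
    transition matrices P(t) and their time derivatives cheaply."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        sq = np.sqrt(np.maximum(pi, 1e-300))
        B = Q * sq[:, None] / sq[None, :]
        B = (B + B.T) / 2.0
        w, V = np.linalg.eigh(B)
        self.w = w
        self.left = V / sq[:, None]
        self.right = V.T * sq[None, :]

    def P(self, t: float) -> np.ndarray:
        E = np.exp(self.w * t)
        P = (self.left * E) @ self.right
        return np.maximum(P, 0.0)

    def P_dP(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        E = np.exp(self.w * t)
        P = (self.left * E) @ self.right
        dP = (self.left * (self.w * E)) @ self.right
        return np.maximum(P, 0.0), dP


# ---------------------------------------------------------------------------
# codon frequency estimation


def estimate_codon_freqs(alignment: CodonAlignment, method: str = "f3x4") -> np.ndarray:
    """Estimate stationary codon frequencies from an alignment.

    ``f61``: empirical sense-codon frequencies (0.5 pseudocount);
    ``f3x4``: products of position-specific nucleotide frequencies,
    renormalised over sense codons (the conventional default);
    ``f1x4``: overall nucleotide frequencies; ``equal``: uniform.
    """
    if method == "equal":
        return np.full(N_STATES, 1.0 / N_STATES)
    codon_counts = np.zeros(N_STATES)
    pos_nt = np.zeros((3, 4))
    nt_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    for _, seq in alignment:
        for i in range(0, len(seq), 3):
            codon = seq[i:i + 3]
            if any(ch not in "ACGT" for ch in codon):
                continue
            for pos, ch in enumerate(codon):
                pos_nt[pos, nt_index[ch]] += 1
            if codon in CODON_INDEX:
                codon_counts[CODON_INDEX[codon]] += 1
    if method == "f61":
        freqs = codon_counts + 0.5
        return freqs / freqs.sum()
    if method == "f1x4":
        nt = pos_nt.sum(axis=0)
        nt = (nt + 1.0) / (nt + 1.0).sum()
        probs = nt[CODON_NT_INDEX].prod(axis=1)
        return probs / probs.sum()
    if method == "f3x4":
        pos = (pos_nt + 1.0) / (pos_nt + 1.0).sum(axis=1, keepdims=True)
        probs = (
            pos[0, CODON_NT_INDEX[:, 0]]
            * pos[1, CODON_NT_INDEX[:, 1]]
            * pos[2, CODON_NT_INDEX[:, 2]]
        )
        return probs / probs.sum()
    raise ValueError(f"unknown frequency method {method!r}")


# ---------------------------------------------------------------------------
# data encoding


def _encode(alignment: CodonAlignment, tree: Phylogeny) -> tuple[np.ndarray, np.ndarray, int]:
    """Site-pattern encoding in tree tip order.

    Returns (codes, counts, n_excluded) where codes is (n_tips, n_patterns)
    with -1 for masked (stop) entries. Columns with gaps/ambiguity anywhere
    are excluded entirely.
    """
    tips = tree.tip_labels
    missing = set(tips) - set(alignment.species)
    extra = set(alignment.species) - set(tips)
    if missing or extra:
        raise ValueError(
            f"tree/alignment species mismatch (missing from alignment: {sorted(missing)}; "
            f"not in tree: {sorted(extra)})"
        )
    n_codons = alignment.n_codons
    mat = np.full((len(tips), n_codons), -2, dtype=np.int64)
    n_stops = 0
    for r, sp in enumerate(tips):
        seq = alignment.seqs[sp]
        for c in range(n_codons):
            codon = seq[3 * c: 3 * c + 3]
            if codon in CODON_INDEX:
                mat[r, c] = CODON_INDEX[codon]
            elif codon in STOP_CODONS:
                mat[r, c] = -1  # masked as missing for this species
                n_stops += 1
            else:
                mat[r, c] = -2  # gap/ambiguity -> column excluded
    keep = ~(mat == -2).any(axis=0)
    if n_stops:
        warnings.warn(
            f"{n_stops} stop codon(s) masked as missing data (pseudogene input)",
            stacklevel=2,
        )
    mat = mat[:, keep]
    n_excluded = n_codons - mat.shape[1]
    if mat.shape[1] == 0:
        raise ValueError("no usable codon columns after filtering")
    patterns, counts = np.unique(mat, axis=1, return_counts=True)
    return patterns, counts.astype(float), n_excluded


# ---------------------------------------------------------------------------
# pruning likelihood (+ analytic branch-length gradient)


def _pruning(
    tree: Phylogeny,
    codes: np.ndarray,
    counts: np.ndarray,
    tms: Sequence[_ClassTM | None],
    lengths: np.ndarray,
    pi: np.ndarray,
    want_grad: bool = False,
) -> tuple[float, np.ndarray | None]:
    npat = codes.shape[1]
    n = tree.n_nodes
    tipmap = {v: i for i, v in enumerate(tree.tip_indices)}
    L: list[np.ndarray | None] = [None] * n
    lsc: list[np.ndarray | None] = [None] * n
    M: list[np.ndarray | None] = [None] * n
    P_cache: list[np.ndarray | None] = [None] * n
    dP_cache: list[np.ndarray | None] = [None] * n

    for v in tree.postorder:
        if not tree.children[v]:
            arr = np.zeros((N_STATES, npat))
            code = codes[tipmap[v]]
            miss = code < 0
            arr[:, miss] = 1.0
            obs = np.flatnonzero(~miss)
            arr[code[obs], obs] = 1.0
            L[v] = arr
            lsc[v] = np.zeros(npat)
        else:
            prod = None
            sc = np.zeros(npat)
            for c in tree.children[v]:
                if want_grad:
                    P, dP = tms[c].P_dP(lengths[c])
                    dP_cache[c] = dP
                else:
                    P = tms[c].P(lengths[c])
                P_cache[c] = P
                M[c] = P @ L[c]
                prod = M[c].copy() if prod is None else prod * M[c]
                sc = sc + lsc[c]
            mx = prod.max(axis=0)
            mx = np.where(mx > 0, mx, 1.0)
            L[v] = prod / mx
            lsc[v] = sc + np.log(mx)

    root = tree.root
    S = pi @ L[root]
    if np.any(S <= 0):
        raise FloatingPointError("zero site likelihood encountered")
    site_log = np.log(S) + lsc[root]
    logL = float(counts @ site_log)
    if not np.isfinite(logL):
        raise FloatingPointError("non-finite log-likelihood")
    if not want_grad:
        return logL, None

    # preorder pass for d logL / d t_v
    grad = np.zeros(n)
    R: list[np.ndarray | None] = [None] * n
    rs: list[np.ndarray | None] = [None] * n
    R[root] = np.repeat(pi[:, None], npat, axis=1)
    rs[root] = np.zeros(npat)
    for u in reversed(tree.postorder):  # preorder
        if not tree.children[u]:
            continue
        kids = tree.children[u]
        for v in kids:
            sibprod = None
            sibsc = np.zeros(npat)
            for w in kids:
                if w == v:
                    continue
                sibprod = M[w].copy() if sibprod is None else sibprod * M[w]
                sibsc = sibsc + lsc[w]
            T = R[u] if sibprod is None else R[u] * sibprod
            rsT = rs[u] + sibsc
            term = np.einsum("ip,ip->p", T, dP_cache[v] @ L[v])
            grad[v] = float(counts @ (term / S * np.exp(rsT + lsc[v] - lsc[root])))
            if tree.children[v]:  # only internals need R
                Rv = P_cache[v].T @ T
                mx = Rv.max(axis=0)
                mx = np.where(mx > 0, mx, 1.0)
                R[v] = Rv / mx
                rs[v] = rsT + np.log(mx)
    return logL, grad


def codon_log_likelihood(
    alignment: CodonAlignment,
    tree: Phylogeny,
    partition: BranchPartition | None = None,
    model: CodonModel | None = None,
    branch_lengths: np.ndarray | Mapping[int, float] | None = None,
) -> float:
    """Log-likelihood of a codon alignment under per-class GY94 matrices."""
    if model is None:
        raise ValueError("model is required")
    partition = partition or BranchPartition()
    codes, counts, _ = _encode(alignment, tree)
    classes = partition.resolved_classes(tree)
    lengths = _resolve_lengths(tree, branch_lengths)
    tms = _class_tms(model, classes, tree)
    logL, _ = _pruning(tree, codes, counts, tms, lengths, model.codon_freqs)
    return logL


def _resolve_lengths(tree: Phylogeny, branch_lengths) -> np.ndarray:
    if branch_lengths is None:
        return tree.lengths.copy()
    if isinstance(branch_lengths, Mapping):
        out = tree.lengths.copy()
        for v, t in branch_lengths.items():
            out[v] = t
        return out
    arr = np.asarray(branch_lengths, dtype=float)
    if arr.shape != (tree.n_nodes,):
        raise ValueError("branch_lengths must have one entry per node")
    return arr


def _class_tms(model: CodonModel, classes: Sequence[str], tree: Phylogeny) -> list:
    unique = sorted({classes[v] for v in range(tree.n_nodes) if v != tree.root})
    built = {c: _ClassTM(build_codon_rate_matrix(model, c), model.codon_freqs) for c in unique}
    return [built.get(classes[v]) if v != tree.root else None for v in range(tree.n_nodes)]


# ---------------------------------------------------------------------------
# maximum-likelihood fitting

_LOG_T_LO, _LOG_T_HI = np.log(1e-8), np.log(50.0)
_LOG_K_LO, _LOG_K_HI = np.log(1e-3), np.log(100.0)
_LOG_W_LO, _LOG_W_HI = np.log(1e-6), np.log(50.0)


def fit_branch_model(
    alignment: CodonAlignment,
    tree: Phylogeny,
    partition: BranchPartition | None = None,
    *,
    freq_model: str = "f3x4",
    n_starts: int = 3,
    seed: int | None = 0,
    init: ModelFit | Mapping | None = None,
    maxiter: int = 500,
) -> ModelFit:
    """Jointly maximise the likelihood over kappa, free omegas and branch
    lengths, honouring fixed / tied class constraints.

    ``init`` may be a previous :class:`ModelFit` (e.g. a null fit used to
    warm-start the alternative so nesting holds numerically) or a mapping
    with any of ``kappa``, ``omega`` (scalar or per-class), ``lengths``.
    """
    partition = partition or BranchPartition()
    codes, counts, n_excluded = _encode(alignment, tree)
    classes = partition.resolved_classes(tree)
    used = [classes[v] for v in range(tree.n_nodes) if v != tree.root]
    free_classes, resolver = partition.free_and_bound(used)
    pi = estimate_codon_freqs(alignment, freq_model)
    edges = [v for v in range(tree.n_nodes) if v != tree.root]
    n_edges = len(edges)
    nw = len(free_classes)

    def unpack(theta: np.ndarray):
        kappa = float(np.exp(theta[0]))
        wfree = {c: float(np.exp(theta[1 + i])) for i, c in enumerate(free_classes)}
        omegas: dict[str, float] = {}
        for c in dict.fromkeys(used):
            kind, val = resolver[c]
            if kind == "free":
                omegas[c] = wfree[c]
            elif kind == "fixed":
                omegas[c] = val
            else:  # tied: target is either a free parameter or itself fixed
                if val in wfree:
                    omegas[c] = wfree[val]
                else:
                    tspec = partition.constraints.get(val, "free")
                    if isinstance(tspec, tuple) and tspec[0] == "fixed":
                        omegas[c] = float(tspec[1])
                    else:
                        raise ValueError(f"unresolvable tie target {val!r}")
        lengths = np.zeros(tree.n_nodes)
        lengths[edges] = np.exp(theta[1 + nw:])
        return kappa, omegas, lengths

    def loglik(theta: np.ndarray, want_grad: bool):
        kappa, omegas, lengths = unpack(theta)
        model = CodonModel(kappa=kappa, omega_by_class=omegas, codon_freqs=pi)
        tms = _class_tms(model, classes, tree)
        return _pruning(tree, codes, counts, tms, lengths, pi, want_grad=want_grad)

    h = 1e-5

    def objective(theta: np.ndarray):
        try:
            logL, grad_t = loglik(theta, True)
        except FloatingPointError:
            return 1e12, np.zeros_like(theta)
        g = np.zeros_like(theta)
        # analytic branch-length gradient (chain rule through log lengths)
        _, _, lengths = unpack(theta)
        g[1 + nw:] = grad_t[edges] * lengths[edges]
        # finite differences for kappa and free omegas (cheap, few params)
        for k in range(1 + nw):
            tp = theta.copy(); tp[k] += h
            tm_ = theta.copy(); tm_[k] -= h
            lp, _ = loglik(tp, False)
            lm, _ = loglik(tm_, False)
            g[k] = (lp - lm) / (2 * h)
        return -logL, -g

    rng = np.random.default_rng(seed)
    base = _initial_theta(tree, edges, free_classes, init, resolver)
    bounds = (
        [(_LOG_K_LO, _LOG_K_HI)]
        + [(_LOG_W_LO, _LOG_W_HI)] * nw
        + [(_LOG_T_LO, _LOG_T_HI)] * n_edges
    )
    best = None
    for s in range(max(1, n_starts)):
        theta0 = base.copy()
        if s > 0:
            theta0[: 1 + nw] += rng.normal(0, 0.5, size=1 + nw)
            theta0[1 + nw:] += rng.normal(0, 0.3, size=n_edges)
        theta0 = np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(
            objective, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
            options=dict(maxiter=maxiter, ftol=1e-12, gtol=1e-7),
        )
        cand = (-res.fun, -np.linalg.norm(res.x), res)
        if best is None or cand[:2] > best[:2]:
            best = cand
    res = best[2]
    kappa, omegas, lengths = unpack(res.x)
    model = CodonModel(kappa=kappa, omega_by_class=omegas, codon_freqs=pi)
    n_params = 1 + nw + n_edges
    return ModelFit(
        model=model,
        branch_lengths=lengths,
        logL=float(-res.fun),
        n_params=n_params,
        converged=bool(res.success),
        partition=partition,
        details=dict(
            freq_model=freq_model,
            n_excluded_columns=n_excluded,
            n_starts=max(1, n_starts),
            optimizer_message=str(res.message),
        ),
    )


def _initial_theta(tree, edges, free_classes, init, resolver) -> np.ndarray:
    kappa0, omega0 = 2.0, 0.4
    lengths0 = np.clip(tree.lengths[edges], 1e-4, 40.0)
    omegas0 = {c: omega0 for c in free_classes}
    if isinstance(init, ModelFit):
        kappa0 = init.model.kappa
        for c in free_classes:
            if c in init.model.omega_by_class:
                omegas0[c] = max(init.model.omega_by_class[c], 1e-5)
            elif init.model.omega_by_class:
                omegas0[c] = max(np.mean(list(init.model.omega_by_class.values())), 1e-5)
        lengths0 = np.clip(init.branch_lengths[edges], 1e-6, 40.0)
    elif isinstance(init, Mapping):
        kappa0 = float(init.get("kappa", kappa0))
        w = init.get("omega", omega0)
        if isinstance(w, Mapping):
            omegas0 = {c: float(w.get(c, omega0)) for c in free_classes}
        else:
            omegas0 = {c: float(w) for c in free_classes}
        if "lengths" in init:
            lengths0 = np.clip(np.asarray(init["lengths"], dtype=float)[edges], 1e-6, 40.0)
    return np.concatenate(
        [[np.log(kappa0)], np.log([omegas0[c] for c in free_classes]), np.log(lengths0)]
    )


def likelihood_ratio_test(
    fit_alt: ModelFit, fit_null: ModelFit, df: int | None = None, tol: float = 1e-3
) -> tuple[float, float]:
    """2*(logL_alt - logL_null) against a chi-square upper tail.

    ``df`` defaults to the difference in free-parameter counts. A null
    likelihood exceeding the alternative beyond ``tol`` violates nesting.
    """
    delta = fit_alt.logL - fit_null.logL
    if delta < -tol:
        raise ValueError(
            f"nesting violation: logL_alt ({fit_alt.logL:.6f}) < logL_null "
            f"({fit_null.logL:.6f})"
        )
    if df is None:
        df = fit_alt.n_params - fit_null.n_params
    if df <= 0:
        raise ValueError("df must be positive")
    stat = max(0.0, 2.0 * delta)
    return stat, float(chi2.sf(stat, df))
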