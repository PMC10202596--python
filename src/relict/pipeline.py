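"""End-to-end orchestration: simulate or ingest -> scan -> fit -> classify -> regress.

The pipeline composes the analysis stages into a reproducible run: with no
input paths it simulates a complete synthetic study (a foreground "aquatic"
clade with relaxed dN/dS, injected lesions, suppressed expression, and
status-associated dive/diet predictors); with paths it ingests FASTA/Newick/
TSV inputs for the corresponding stages. Identical config + seed yields
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import expression_stats, lesion_scan, status_integration, trait_models
from .alignment import CodonAlignment
from .codon_selection import BranchPartition, fit_branch_model, likelihood_ratio_test
from .lesion_scan import DEFAULT_PON1_CATALOG, SiteCatalog
from .status_integration import EvidenceRecord, StatusThresholds, classify_all
from .synthetic_data import (
    SimConfig,
    generate_yule_tree,
    inject_lesions,
    pick_foreground_clade,
    simulate_codon_alignment,
    simulate_expression_table,
)
from .trees import Phylogeny

log = logging.getLogger("relict")

ALL_STAGES = ("simulate", "scan", "selection", "expression", "status", "traits")

#: which stages each stage needs (outputs usable from files or earlier stages)
_STAGE_NEEDS = {
    "simulate": (),
    "scan": ("alignment",),
    "selection": ("alignment", "tree"),
    "expression": ("expression_table",),
    "status": ("scan", "expression"),
    "traits": ("status", "tree"),
}


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "relict_out"
    stages: tuple[str, ...] = ALL_STAGES
    # synthetic study conditions
    n_tips: int = 12
    n_codons: int = 300
    kappa: float = 2.0
    omega_background: float = 0.2
    omega_foreground: float = 0.8
    tree_height: float = 0.4
    expression_sd: float = 0.8
    alpha_signal: float = 8.0
    # analysis options
    freq_model: str = "f3x4"
    n_starts: int = 1
    alpha_bounds: tuple[float, float] = (1e-3, 1e3)
    thresholds: StatusThresholds = field(default_factory=StatusThresholds)
    catalog_positions: tuple[int, ...] = (10, 25, 40, 55, 70)
    # optional ingestion paths (override the synthetic stage products)
    inputs: dict = field(default_factory=dict)

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for path in self.inputs.values():
            if not Path(path).exists():
                raise FileNotFoundError(path)
        available = set(self.inputs)
        if "simulate" in self.stages:
            available |= {"alignment", "tree", "expression_table", "scan", "expression",
                          "status"}
        done = set()
        for stage in self.stages:
            for need in _STAGE_NEEDS[stage]:
                if need not in available and need not in done:
                    raise ValueError(
                        f"stage {stage!r} needs {need!r}: enable an earlier stage or "
                        f"provide an input path"
                    )
            done.add(stage)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "thresholds" in raw:
            raw["thresholds"] = StatusThresholds(**raw["thresholds"])
        for key in ("stages", "catalog_positions", "alpha_bounds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["thresholds"] = dataclasses.asdict(self.thresholds)
        raw["stages"] = list(self.stages)
        raw["catalog_positions"] = list(self.catalog_positions)
        raw["alpha_bounds"] = list(self.alpha_bounds)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass
class RunReport:
    seed: int
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def record(self, stage: str, params: dict, outputs: dict[str, str]) -> None:
        digests = {
            name: hashlib.sha256(Path(p).read_bytes()).hexdigest()[:16]
            for name, p in outputs.items()
        }
        # store file names only, so reports are portable across out_dirs
        self.stages[stage] = dict(
            params=params,
            outputs={name: Path(p).name for name, p in outputs.items()},
            digests=digests,
        )

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                dict(seed=self.seed, stages=self.stages, warnings=self.warnings),
                fh, indent=2, sort_keys=True,
            )


def _rng(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(100 + key,)))


def run_pipeline(config: PipelineConfig) -> RunReport:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)
    state: dict = {}

    for stage in config.stages:
        log.info("stage %s (seed %d)", stage, config.seed)
        try:
            _STAGE_RUNNERS[stage](config, state, report, out)
        except Exception:
            report.warnings.append(f"stage {stage} failed; downstream stages skipped")
            report.write(out / "run_report.json")
            raise
    report.write(out / "run_report.json")
    return report


# ---------------------------------------------------------------------------
# stage implementations


def _load_tree(config: PipelineConfig, state: dict) -> Phylogeny:
    if "tree" in state:
        return state["tree"]
    tree = Phylogeny.from_newick(Path(config.inputs["tree"]).read_text())
    state["tree"] = tree
    return tree


def _stage_simulate(config: PipelineConfig, state: dict, report: RunReport, out: Path) -> None:
    sim = SimConfig(
        seed=config.seed,
        n_tips=config.n_tips,
        n_codons=config.n_codons,
        kappa=config.kappa,
        omega_by_class={"bg": config.omega_background, "fg": config.omega_foreground},
        expression_sd=config.expression_sd,
        alpha_signal=config.alpha_signal,
    )
    tree = generate_yule_tree(config.n_tips, config.seed).with_height(config.tree_height)
    aquatic = pick_foreground_clade(tree, 0.4)
    tree = tree.tag_clade(aquatic, "fg")
    alignment = simulate_codon_alignment(tree, sim)
    # reference numbering must come from an unlesioned (terrestrial) species
    terrestrial = [sp for sp in tree.tip_labels if sp not in aquatic]
    alignment.ref_species = terrestrial[0]

    # lesions go into (a subset of) the aquatic clade
    catalog_positions = [p for p in config.catalog_positions if p <= config.n_codons - 1]
    if not catalog_positions:
        raise ValueError("no catalog position fits inside the simulated gene")
    rng = _rng(config.seed, 1)
    plan = []
    for i, sp in enumerate(sorted(aquatic)):
        kind = ("premature_stop", "frameshift", "critical_site_sub")[i % 3]
        pos = (
            int(rng.integers(2, config.n_codons))
            if kind != "critical_site_sub"
            else int(rng.choice(catalog_positions))
        )
        plan.append((sp, kind, pos))
    alignment, truth = inject_lesions(alignment, plan, seed=config.seed)

    clades = {sp: ("aquatic" if sp in aquatic else "terrestrial") for sp in tree.tip_labels}
    expr = simulate_expression_table(clades, sim)

    # predictors: dive capacity high in the aquatic clade, diet weakly shifted
    rows = {}
    for sp in tree.tip_labels:
        aq = sp in aquatic
        rows[sp] = dict(
            dive_capacity=float(rng.normal(8.0 if aq else 2.0, 1.0)),
            diet_omega3_fraction=float(np.clip(rng.normal(0.55 if aq else 0.45, 0.1), 0, 1)),
        )
    predictors = pd.DataFrame.from_dict(rows, orient="index").sort_index()

    catalog = SiteCatalog.from_pairs(
        [
            (p, lesion_scan.translate_codon(alignment.seqs[alignment.ref_species][3 * (p - 1):3 * p]))
            for p in catalog_positions
        ]
    )

    paths = dict(
        alignment=str(out / "alignment.fasta"),
        tree=str(out / "tree.nwk"),
        expression=str(out / "expression.tsv"),
        predictors=str(out / "predictors.tsv"),
        truth=str(out / "truth.json"),
        catalog=str(out / "catalog.tsv"),
    )
    alignment.write_fasta(paths["alignment"])
    Path(paths["tree"]).write_text(tree.to_newick() + "\n")
    expr.to_csv(paths["expression"], sep="\t", index=False)
    predictors.to_csv(paths["predictors"], sep="\t", index_label="species")
    catalog.write_tsv(paths["catalog"])
    with open(paths["truth"], "w") as fh:
        json.dump(
            dict(
                lesions=[list(l) for l in truth.true_lesions],
                omegas={"bg": config.omega_background, "fg": config.omega_foreground},
                aquatic=sorted(aquatic),
            ),
            fh, indent=2, sort_keys=True,
        )
    state.update(
        tree=tree, alignment=alignment, expression=expr, predictors=predictors,
        truth=truth, aquatic=aquatic, catalog=catalog,
    )
    report.record(
        "simulate",
        dict(n_tips=config.n_tips, n_codons=config.n_codons,
             omega=dict(bg=config.omega_background, fg=config.omega_foreground)),
        paths,
    )


def _stage_scan(config: PipelineConfig, state: dict, report: RunReport, out: Path) -> None:
    if "alignment" not in state:
        state["alignment"] = CodonAlignment.read_fasta(config.inputs["alignment"])
        ref = config.inputs.get("ref_species")
        state["alignment"].ref_species = ref or state["alignment"].species[0]
    catalog = state.get("catalog")
    if catalog is None and "catalog" in config.inputs:
        catalog = SiteCatalog.read_tsv(config.inputs["catalog"])
    catalog = catalog or DEFAULT_PON1_CATALOG
    scan = lesion_scan.scan_alignment(state["alignment"], catalog)
    paths = dict(lesions=str(out / "lesions.tsv"), lesion_summary=str(out / "lesions.json"))
    scan.write_tsv(paths["lesions"])
    scan.write_json_summary(paths["lesion_summary"])
    state["scan"] = scan
    report.record("scan", dict(n_catalog_sites=len(catalog)), paths)


def _stage_selection(config: PipelineConfig, state: dict, report: RunReport, out: Path) -> None:
    tree = _load_tree(config, state)
    alignment = state["alignment"]
    # single-class null first; the two-class alternative is warm-started from
    # it so the nesting inequality holds numerically
    null = fit_branch_model(
        alignment, tree, BranchPartition.single("all"),
        freq_model=config.freq_model, n_starts=config.n_starts, seed=config.seed,
    )
    alt = fit_branch_model(
        alignment, tree, BranchPartition(),
        freq_model=config.freq_model, n_starts=config.n_starts, seed=config.seed,
        init=null,
    )
    stat, p = likelihood_ratio_test(alt, null)
    result = dict(
        omega_by_class=alt.model.omega_by_class,
        omega_single=null.model.omega_by_class,
        kappa=alt.model.kappa,
        logL_alt=alt.logL,
        logL_null=null.logL,
        lrt_statistic=stat,
        lrt_p=p,
        df=alt.n_params - null.n_params,
        converged=bool(alt.converged and null.converged),
    )
    branch_rows = []
    label = {v: lbl for v, lbl in zip(tree.tip_indices, tree.tip_labels)}
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        branch_rows.append(
            dict(node=label.get(v, f"node{v}"), branch_class=tree.classes[v],
                 input_length=float(tree.lengths[v]),
                 fitted_length=float(alt.branch_lengths[v]))
        )
    paths = dict(selection=str(out / "selection.json"),
                 branches=str(out / "branch_table.tsv"))
    with open(paths["selection"], "w") as fh:
        json.dump(result, fh, indent=2, sort_keys=True)
    pd.DataFrame(branch_rows).to_csv(paths["branches"], sep="\t", index=False)
    state["selection"] = result
    report.record("selection", dict(freq_model=config.freq_model), paths)


def _stage_expression(config: PipelineConfig, state: dict, report: RunReport, out: Path) -> None:
    if "expression" not in state:
        state["expression"] = pd.read_csv(config.inputs["expression_table"], sep="\t")
    expr = state["expression"]
    means = expression_stats.average_by_species(expr, "Pon1")
    groups = expr.groupby("clade")["species"].unique().to_dict()
    result: dict = {"species_means": {k: float(v) for k, v in means.items()}}
    if {"terrestrial", "aquatic"} <= set(groups):
        a = [means[s] for s in sorted(groups["terrestrial"]) if s in means]
        b = [means[s] for s in sorted(groups["aquatic"]) if s in means]
        test = expression_stats.mann_whitney_test(a, b)
        result["pon1_contrast"] = dict(
            U=test.U, Z=test.Z, p=test.p, n1=test.n1, n2=test.n2, method=test.method
        )
    paths = dict(expression=str(out / "expression_stats.json"))
    with open(paths["expression"], "w") as fh:
        json.dump(result, fh, indent=2, sort_keys=True)
    state["expression_result"] = result
    state["species_means"] = means
    report.record("expression", dict(gene="Pon1"), paths)


def _stage_status(config: PipelineConfig, state: dict, report: RunReport, out: Path) -> None:
    summary = state["scan"].summary() if "scan" in state else {}
    means = state.get("species_means", {})
    species = sorted(set(summary) | set(means))
    records = []
    for sp in species:
        flags = summary.get(sp, {})
        records.append(
            EvidenceRecord(
                species=sp,
                any_lesion=flags.get("any_lesion"),
                any_critical_sub=flags.get("any_critical_sub"),
                mean_tpm=means.get(sp),
            )
        )
    calls = classify_all(records, config.thresholds)
    paths = dict(status=str(out / "status.tsv"))
    status_integration.write_status_tsv(calls, paths["status"])
    state["status_calls"] = calls
    report.record(
        "status",
        dict(tpm_present=config.thresholds.tpm_present,
             tpm_absent=config.thresholds.tpm_absent),
        paths,
    )


def _stage_traits(config: PipelineConfig, state: dict, report: RunReport, out: Path) -> None:
    tree = _load_tree(config, state)
    if "predictors" not in state:
        state["predictors"] = pd.read_csv(
            config.inputs["predictors"], sep="\t", index_col="species"
        )
    table = status_integration.build_trait_table(state["status_calls"], state["predictors"])
    # prune the tree to the species retained in the table
    keep = set(table.index)
    pruned = _prune_to(tree, keep)
    fits = []
    groups = {}
    for trait in table.columns.drop("status"):
        fit = trait_models.fit_phylo_logistic(
            pruned,
            {sp: int(table.loc[sp, "status"]) for sp in pruned.tip_labels},
            {sp: float(table.loc[sp, trait]) for sp in pruned.tip_labels},
            alpha_bounds=config.alpha_bounds,
            trait_name=trait,
        )
        fits.append((trait, fit))
        groups[trait] = "diving" if "dive" in trait else "diet"
    ranking = trait_models.rank_models_aic(fits, groups)
    paths = dict(
        trait_table=str(out / "trait_table.tsv"),
        ranking=str(out / "trait_ranking.tsv"),
    )
    table.to_csv(paths["trait_table"], sep="\t")
    ranking.to_csv(paths["ranking"], sep="\t", index=False)
    state["trait_ranking"] = ranking
    report.record("traits", dict(traits=list(groups)), paths)


def _prune_to(tree: Phylogeny, keep: set[str]) -> Phylogeny:
    dt = tree.to_dendropy()
    taxa = [t for t in dt.taxon_namespace if t.label in keep]
    dt.retain_taxa(taxa)
    dt.purge_taxon_namespace()
    return Phylogeny.from_dendropy(dt)


_STAGE_RUNNERS = {
    "simulate": _stage_simulate,
    "scan": _stage_scan,
    "selection": _stage_selection,
    "expression": _stage_expression,
    "status": _stage_status,
    "traits": _stage_traits,
}
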