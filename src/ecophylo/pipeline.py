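"""Configuration-driven orchestration of the full comparative analysis.

A :class:`RunConfig` (usually loaded from a YAML file) names either a
``synthetic`` block (simulation knobs) or on-disk inputs (tree, rasters,
occurrences, traits, alignments), plus the analysis settings.
:func:`run_pipeline` executes the requested stages in dependency order —

    thin occurrences -> AUC filter -> overlap matrices
        -> node means -> age-overlap regression -> mode classification
    traits -> Blomberg's K / PCA / Mk1 ASR / stochastic maps
    alignments -> pi / Ka/Ks table

— and returns a :class:`Report` whose tables :func:`write_report` writes
as CSV/JSON with a human-readable summary.  Per-stage seeds are derived
from the master seed by stable hashing, so enabling or disabling one
stage never shifts another stage's random stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import molevol, niche, signal, simulate
from .age_overlap import AgeOverlapModel
from .mk import Mk1Model
from .trees import node_ages, parse_newick

__all__ = ["RunConfig", "Report", "load_config", "run_pipeline", "write_report"]

ALL_STAGES = ("overlap", "age_overlap", "signal", "asr", "kaks")


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    synthetic: simulate.SimConfig | None = None
    tree_path: str | None = None
    raster_dir: str | None = None
    occurrence_path: str | None = None
    trait_path: str | None = None
    alignment_paths: tuple[str, ...] = ()
    basis: tuple[str, ...] = ("range", "point")
    n_perm: int = 1000
    auc_threshold: float = 0.8
    thinning_block: int = 1
    slope_tol: float = 0.0
    discrete_traits: tuple[str, ...] = ()
    focal_state: int = 1
    n_maps: int = 1000
    min_gene_length: int = 300

    def __post_init__(self) -> None:
        bad = [s for s in self.stages if s not in ALL_STAGES]
        if bad:
            raise ValueError(f"unknown stage(s): {bad}")
        if not self.stages:
            raise ValueError("at least one stage must be enabled")

    def canonical(self) -> str:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
        return json.dumps(d, sort_keys=True, default=str)

    def hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "synthetic" in raw and raw["synthetic"] is not None:
        syn = dict(raw["synthetic"])
        if "grid_shape" in syn:
            syn["grid_shape"] = tuple(syn["grid_shape"])
        raw["synthetic"] = simulate.SimConfig(**syn)
    for key in ("stages", "basis", "alignment_paths", "discrete_traits"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


@dataclass
class Report:
    config_hash: str
    seed: int
    stages_run: list[str] = field(default_factory=list)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    json_results: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    summaries: list[str] = field(default_factory=list)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


# ------------------------------------------------------------------ loading

def _load_inputs(config: RunConfig):
    """Resolve synthetic or on-disk inputs into in-memory objects."""
    need_overlap = bool({"overlap", "age_overlap"} & set(config.stages))
    need_traits = bool({"signal", "asr"} & set(config.stages))
    need_genes = "kaks" in config.stages

    tree = grids = occs = traits = None
    alignments: list[molevol.CodonAlignment] = []

    if config.synthetic is not None:
        sim = config.synthetic
        tree = simulate.simulate_tree(sim)
        if need_overlap:
            _, _, raw = simulate.simulate_landscape(tree, sim)
            grids = [niche.SuitabilityGrid(species=sp, values=g, auc=1.0)
                     for sp, g in raw.items()]
            occs = {}
            base = config.stage_seed("occurrences")
            for i, sp in enumerate(tree.tip_labels):
                occs[sp] = simulate.sample_occurrences(
                    raw[sp], sim.n_occurrences, seed=base + i, species=sp)
        if need_traits:
            cont = simulate.simulate_trait(tree, "continuous", sim,
                                           seed=config.stage_seed("trait_cont"))
            disc = simulate.simulate_trait(tree, "discrete", sim,
                                           seed=config.stage_seed("trait_disc"))
            traits = pd.DataFrame({"trait_cont": cont, "trait_disc": disc},
                                  index=tree.tip_labels)
        if need_genes:
            alignments = [simulate.simulate_codon_alignment(
                tree, sim, seed=config.stage_seed("codons"), gene="gene1")]
    else:
        if config.tree_path:
            tree = parse_newick(Path(config.tree_path).read_text())
        if need_overlap:
            if tree is None or config.raster_dir is None:
                raise StageError("overlap", "tree and raster_dir are required")
            grids = []
            for sp in tree.tip_labels:
                p = Path(config.raster_dir) / f"{sp}.csv"
                if not p.exists():
                    raise StageError("overlap", f"no raster for tip {sp!r}")
                grids.append(niche.SuitabilityGrid(
                    species=sp, values=simulate.read_raster_csv(p), auc=1.0))
            occs = {}
            if config.occurrence_path:
                df = pd.read_csv(config.occurrence_path)
                for sp, sub in df.groupby("species"):
                    occs[sp] = simulate.OccurrenceSet(
                        species=str(sp),
                        cells=list(zip(sub["row"].astype(int),
                                       sub["col"].astype(int))))
        if need_traits:
            if config.trait_path is None:
                raise StageError("signal", "trait_path is required")
            traits = pd.read_csv(config.trait_path, index_col=0)
        if need_genes:
            from Bio import SeqIO
            for path in config.alignment_paths:
                records = [(rec.id, str(rec.seq).upper())
                           for rec in SeqIO.parse(path, "fasta")]
                pseudo = Path(path).stem.endswith(".pseudo")
                alignments.append(molevol.CodonAlignment(
                    gene=Path(path).stem, records=records, pseudogene=pseudo))
    return tree, grids, occs, traits, alignments


# ------------------------------------------------------------------ stages

def _stage_overlap(config: RunConfig, tree, grids, occs, report: Report):
    grids = niche.filter_models(grids, threshold=config.auc_threshold)
    if len(grids) < 2:
        raise StageError("overlap", "fewer than 2 models passed the AUC filter")
    kept = {g.species for g in grids}
    if tree is not None:
        missing = [t for t in tree.tip_labels if t not in kept]
        if missing:
            raise StageError("overlap", f"tree tip(s) without a retained "
                                        f"suitability model: {missing}")
    thinned = {sp: niche.thin_occurrences(o, config.thinning_block)
               for sp, o in (occs or {}).items()}
    matrices = {}
    for basis in config.basis:
        try:
            matrices[basis] = niche.overlap_matrix(
                grids, occurrences=thinned if basis == "point" else None,
                basis=basis)
        except ValueError as exc:
            raise StageError("overlap", str(exc)) from exc
        df = matrices[basis].to_dataframe()
        report.tables[f"overlap_{basis}"] = df
    report.summaries.append(
        f"overlap: {len(grids)} species, bases {list(config.basis)}, "
        f"thinning block {config.thinning_block}")
    return matrices


def _stage_age_overlap(config: RunConfig, tree, matrices, report: Report):
    for basis, matrix in matrices.items():
        try:
            model = AgeOverlapModel(tree, matrix)
            res = model.fit(n_perm=config.n_perm,
                            seed=config.stage_seed(f"age_overlap_{basis}"),
                            slope_tol=config.slope_tol)
        except ValueError as exc:
            raise StageError("age_overlap", str(exc)) from exc
        report.tables[f"node_overlap_{basis}"] = res.records_dataframe()
        report.json_results[f"age_overlap_{basis}"] = {
            "basis": basis, "intercept": res.intercept, "slope": res.slope,
            "p_slope": res.p_slope, "p_intercept": res.p_intercept,
            "n_perm": res.n_perm, "seed": res.seed,
            "slope_tol": res.slope_tol, "mode": res.mode,
        }
        if abs(res.intercept - 0.5) < 1e-12:
            report.warnings.append(
                f"age_overlap[{basis}]: intercept exactly 0.5 -> non-sympatric")
        report.summaries.append(f"age_overlap[{basis}]: mode={res.mode} "
                                f"(intercept={res.intercept:.3f}, "
                                f"slope={res.slope:.3f}, p={res.p_slope:.3g})")


def _stage_signal(config: RunConfig, tree, traits: pd.DataFrame, report: Report):
    traits = traits.loc[list(tree.tip_labels)]
    rows = []
    for col in traits.columns:
        x = traits[col].to_numpy(dtype=float)
        try:
            res = signal.k_permutation_test(
                tree, x, n_perm=config.n_perm,
                seed=config.stage_seed(f"signal_{col}"), trait_name=col)
            rows.append({"trait": col, "K": res.k_stat, "p": res.p_value,
                         "n_perm": res.n_perm, "seed": res.seed})
        except ValueError as exc:
            report.warnings.append(f"signal[{col}]: skipped ({exc})")
    if not rows:
        raise StageError("signal", "no trait could be analyzed")
    report.tables["blomberg_k"] = pd.DataFrame(rows)
    if traits.shape[1] >= 2:
        pca = signal.trait_pca(traits)
        report.tables["pca_loadings"] = pca.loadings
        report.tables["pca_variance"] = pd.DataFrame(
            {"axis": pca.loadings.columns,
             "variance_fraction": pca.variance_fraction})
    report.summaries.append(
        "signal: K computed for " + ", ".join(r["trait"] for r in rows))


def _stage_asr(config: RunConfig, tree, traits: pd.DataFrame, report: Report):
    traits = traits.loc[list(tree.tip_labels)]
    cols = list(config.discrete_traits) or [
        c for c in traits.columns
        if np.array_equal(traits[c], traits[c].astype(int))]
    if not cols:
        raise StageError("asr", "no discrete trait column found")
    ages = node_ages(tree)
    for col in cols:
        states = traits[col].to_numpy(dtype=int)
        try:
            res = Mk1Model(tree, states).fit()
            asr = res.ancestral_states()
            maps = res.stochastic_maps(config.n_maps,
                                       seed=config.stage_seed(f"asr_{col}"),
                                       focal_state=config.focal_state)
        except ValueError as exc:
            raise StageError("asr", f"{col}: {exc}") from exc
        rows = [{"node": node, "age": float(ages[node]),
                 **{f"p_state{j}": p[j] for j in range(len(p))}}
                for node, p in sorted(asr.node_probs.items())]
        report.tables[f"asr_{col}"] = pd.DataFrame(rows)
        hist = np.bincount(maps.origin_counts)
        report.json_results[f"maps_{col}"] = {
            "q_ml": res.q, "loglik": res.loglik, "n_maps": maps.n_maps,
            "seed": maps.seed, "focal_state": maps.focal_state,
            "transition_mean": maps.transition_mean.tolist(),
            "origin_count_histogram": hist.tolist(),
            "origin_count_mean": float(maps.origin_counts.mean()),
        }
        report.summaries.append(
            f"asr[{col}]: q={res.q:.4g}, mean origins of state "
            f"{maps.focal_state} = {maps.origin_counts.mean():.2f}")


def _stage_kaks(config: RunConfig, alignments, report: Report):
    if not alignments:
        raise StageError("kaks", "no alignments supplied")
    rows = []
    for aln in alignments:
        try:
            pi = (molevol.nucleotide_diversity(aln).pi
                  if len(aln.records) >= 2 else np.nan)
            res = molevol.gene_kaks_summary(aln, min_length=config.min_gene_length)
        except ValueError as exc:
            raise StageError("kaks", f"{aln.gene}: {exc}") from exc
        if res.excluded_reason:
            report.warnings.append(f"kaks[{aln.gene}]: excluded "
                                   f"({res.excluded_reason})")
        if res.ratio is None and not res.excluded_reason:
            report.warnings.append(f"kaks[{aln.gene}]: Ka/Ks undefined")
        rows.append({"gene": aln.gene, "length": aln.length,
                     "n_seqs": len(aln.records), "pi": pi,
                     "S_sites": res.s_sites, "N_sites": res.n_sites,
                     "Ka": res.ka, "Ks": res.ks, "ratio": res.ratio,
                     "class": res.selection_class,
                     "excluded_reason": res.excluded_reason})
    report.tables["kaks"] = pd.DataFrame(rows)
    report.summaries.append(f"kaks: {len(rows)} gene(s) processed")


# --------------------------------------------------------------------- run

def run_pipeline(config: RunConfig) -> Report:
    """Execute the enabled stages in dependency order; abort on stage failure."""
    report = Report(config_hash=config.hash(), seed=config.seed)
    tree, grids, occs, traits, alignments = _load_inputs(config)

    matrices = None
    if "overlap" in config.stages:
        matrices = _stage_overlap(config, tree, grids, occs, report)
        report.stages_run.append("overlap")
    if "age_overlap" in config.stages:
        if matrices is None:
            matrices = _stage_overlap(config, tree, grids, occs, report)
        _stage_age_overlap(config, tree, matrices, report)
        report.stages_run.append("age_overlap")
    if "signal" in config.stages:
        _stage_signal(config, tree, traits, report)
        report.stages_run.append("signal")
    if "asr" in config.stages:
        _stage_asr(config, tree, traits, report)
        report.stages_run.append("asr")
    if "kaks" in config.stages:
        _stage_kaks(config, alignments, report)
        report.stages_run.append("kaks")
    return report


def write_report(report: Report, out_dir: str | Path) -> list[Path]:
    """Write all tables/JSON plus a human-readable summary; idempotent."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in sorted(report.tables.items()):
        p = out / f"{name}.csv"
        df.to_csv(p, index=not isinstance(df.index, pd.RangeIndex))
        written.append(p)
    for name, obj in sorted(report.json_results.items()):
        p = out / f"{name}.json"
        p.write_text(json.dumps(obj, indent=1, sort_keys=True))
        written.append(p)
    lines = ["ecophylo pipeline report",
             "========================",
             f"config hash: {report.config_hash}",
             f"master seed: {report.seed}",
             ""]
    for stage in ALL_STAGES:
        status = "run" if stage in report.stages_run else "skipped"
        lines.append(f"stage {stage:12s} {status}")
    lines.append("")
    lines.extend(report.summaries)
    if report.warnings:
        lines.append("")
        lines.append("warnings:")
        lines.extend(f"  - {w}" for w in report.warnings)
    p = out / "summary.txt"
    p.write_text("\n".join(lines) + "\n")
    written.append(p)
    return written
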