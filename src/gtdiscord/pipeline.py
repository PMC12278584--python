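"""End-to-end pipeline: simulate -> candidate gene trees -> refits ->
preference tests -> species trees -> evaluation -> anomaly scan.

Each stage writes its artifacts (FASTA, newick, TSV, JSON) into a run
directory and can be re-run or resumed independently; stage seeds are
derived from the master seed by fixed offsets so any locus can be replayed
in isolation.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .alignment import CodonAlignment
from .anomaly import detect_anomalous_pairs, difficult_nodes
from .experiment import filter_and_balance, run_battery
from .genetree import (EST1_LABEL, EST2_LABEL, REF_LABEL, GeneRecord,
                       build_gene_record, refit_three_topologies)
from .models import FMutSel0Params, FittedModel, GTRParams, SelACParams
from .simulate import (SimConfig, pick_outgroup, simulate_dataset,
                       write_dataset)
from .speciestree import (SpeciesTreeReport, branch_metrics,
                          estimate_species_tree, evaluate_species_tree)
from .trees import (DistanceRecord, PhyloTree, root_on_outgroup,
                    trim_to_common_taxa)

log = logging.getLogger("gtdiscord")

STAGES = ("simulate", "genetrees", "experiment", "speciestree", "anomaly")

# fixed per-stage seed offsets from the master seed
SEED_OFFSETS = {"simulate": 0, "genetrees": 1_000, "experiment": 2_000,
                "speciestree": 3_000, "anomaly": 4_000}


@dataclass
class PipelineConfig:
    """Declarative configuration of a full run."""

    sim: SimConfig = field(default_factory=SimConfig)
    n_target: int = 40
    alpha: float = 0.05
    seed: int = 0
    n_starts: int = 2
    n_cat: int = 4
    coarse_refits: bool = True
    outgroup: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_target < 2:
            raise ValueError("n_target must be >= 2")

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        sim_kwargs = dict(d.pop("sim", {}))
        for key in ("n_codons_range", "occupancy_range"):
            if sim_kwargs.get(key) is not None:
                sim_kwargs[key] = tuple(sim_kwargs[key])
        return cls(sim=SimConfig(**sim_kwargs), **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("n_codons_range", "occupancy_range"):
            if d["sim"].get(key) is not None:
                d["sim"][key] = list(d["sim"][key])
        return d

    def refit_models(self) -> dict[str, object]:
        """The three refit families: nucleotide GTR plus the two
        selection-based codon models."""
        return {
            "GTR": GTRParams(n_cat=self.n_cat, discretization="median"),
            "FMutSel0": FMutSel0Params(omega=0.5, n_cat=self.n_cat,
                                       discretization="mean"),
            "SelAC": SelACParams(psi=0.02, n_cat=self.n_cat,
                                 discretization="mean"),
        }

    def optimize_params(self) -> dict[str, tuple[str, ...]]:
        # each codon model optimizes its single selection parameter
        return {"FMutSel0": ("omega",), "SelAC": ("psi",)}

    def genetree_models(self) -> tuple[object, object]:
        """Model families for the two estimated gene trees."""
        fam1 = GTRParams(n_cat=self.n_cat, discretization="median")
        fam2 = FMutSel0Params(omega=0.5, n_cat=self.n_cat,
                              discretization="mean")
        return fam1, fam2


def _done(outdir: Path, stage: str) -> Path:
    return outdir / f".{stage}.done"


def _mark(outdir: Path, stage: str) -> None:
    _done(outdir, stage).write_text("done\n")


# --------------------------------------------------------------------------
# stage 1: simulate
# --------------------------------------------------------------------------
def stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    sim = dataclasses.replace(cfg.sim, seed=cfg.seed + SEED_OFFSETS["simulate"]
                              + cfg.sim.seed)
    st, loci = simulate_dataset(sim, outgroup=cfg.outgroup)
    data = outdir / "data"
    write_dataset(data, st, loci)
    outgroup = cfg.outgroup or pick_outgroup(st)
    (data / "outgroup.txt").write_text(outgroup + "\n")
    log.info("simulated %d loci on %d taxa", len(loci), sim.n_taxa)


def load_dataset(outdir: Path) -> tuple[PhyloTree, str, list[CodonAlignment],
                                        dict[str, PhyloTree]]:
    data = outdir / "data"
    st = PhyloTree.from_newick((data / "species_tree.nwk").read_text(),
                               units="coalescent")
    outgroup = (data / "outgroup.txt").read_text().strip()
    alns, gts = [], {}
    manifest = (data / "manifest.tsv").read_text().strip().splitlines()[1:]
    for line in manifest:
        locus_id = line.split("\t")[0]
        alns.append(CodonAlignment.from_fasta(data / f"{locus_id}.fasta"))
        gts[locus_id] = PhyloTree.from_newick(
            (data / f"{locus_id}.genetree.nwk").read_text(),
            units="coalescent")
    return st, outgroup, alns, gts


# --------------------------------------------------------------------------
# stage 2: candidate gene trees + distances
# --------------------------------------------------------------------------
_DIST_FIELDS = [f.name for f in dataclasses.fields(DistanceRecord)]


def stage_genetrees(cfg: PipelineConfig, outdir: Path) -> None:
    st, outgroup, alns, _ = load_dataset(outdir)
    fam1, fam2 = cfg.genetree_models()
    gdir = outdir / "genetrees"
    gdir.mkdir(exist_ok=True)
    rows = ["\t".join(_DIST_FIELDS)]
    base_seed = cfg.seed + SEED_OFFSETS["genetrees"]
    for i, aln in enumerate(alns):
        rec = build_gene_record(aln, st, fam1, fam2, outgroup,
                                seed=base_seed + 10 * i, coarse=True)
        for label, suffix in ((REF_LABEL, "ref"), (EST1_LABEL, "est1"),
                              (EST2_LABEL, "est2")):
            (gdir / f"{aln.locus_id}.{suffix}.nwk").write_text(
                rec.topologies[label].to_newick() + "\n")
        d = rec.distances
        rows.append("\t".join(str(getattr(d, f)) for f in _DIST_FIELDS))
        log.info("locus %s: least discordant %s (agree=%s)", aln.locus_id,
                 d.least_discordant, d.metrics_agree)
    (gdir / "distances.tsv").write_text("\n".join(rows) + "\n")


def load_records(outdir: Path) -> list[GeneRecord]:
    _, _, alns, _ = load_dataset(outdir)
    gdir = outdir / "genetrees"
    lines = (gdir / "distances.tsv").read_text().strip().splitlines()
    header = lines[0].split("\t")
    dist_by_locus = {}
    for line in lines[1:]:
        vals = dict(zip(header, line.split("\t")))
        kwargs = {}
        for f in dataclasses.fields(DistanceRecord):
            v = vals[f.name]
            if f.type in ("int",):
                kwargs[f.name] = int(v)
            elif f.type in ("float",):
                kwargs[f.name] = float(v)
            elif f.type == "bool":
                kwargs[f.name] = v == "True"
            else:
                kwargs[f.name] = v
        dist_by_locus[kwargs["locus_id"]] = DistanceRecord(**kwargs)
    records = []
    for aln in alns:
        topologies = {}
        for label, suffix in ((REF_LABEL, "ref"), (EST1_LABEL, "est1"),
                              (EST2_LABEL, "est2")):
            topologies[label] = PhyloTree.from_newick(
                (gdir / f"{aln.locus_id}.{suffix}.nwk").read_text(),
                units="substitution" if label != REF_LABEL else "coalescent")
        rec = GeneRecord(aln.locus_id, aln, topologies,
                         distances=dist_by_locus[aln.locus_id])
        records.append(rec)
    return records


# --------------------------------------------------------------------------
# stage 3: refits + statistical battery
# --------------------------------------------------------------------------
def stage_experiment(cfg: PipelineConfig, outdir: Path) -> None:
    records = load_records(outdir)
    edir = outdir / "experiment"
    edir.mkdir(exist_ok=True)
    base_seed = cfg.seed + SEED_OFFSETS["experiment"]
    retained = filter_and_balance(records, cfg.n_target, seed=base_seed)
    (edir / "retained.txt").write_text(
        "\n".join(r.locus_id for r in retained) + "\n")
    models = cfg.refit_models()
    opt = cfg.optimize_params()
    fits_dir = edir / "fits"
    fits_dir.mkdir(exist_ok=True)
    for i, rec in enumerate(retained):
        refit_three_topologies(rec, models, n_starts=cfg.n_starts,
                               seed=base_seed + 100 * (i + 1),
                               optimize_params=opt,
                               coarse=cfg.coarse_refits)
        payload = {f"{m}|{t}": fit.to_dict()
                   for (m, t), fit in rec.fits.items()}
        payload["preferred"] = rec.preferred
        (fits_dir / f"{rec.locus_id}.json").write_text(
            json.dumps(payload, indent=1))
        log.info("refit locus %s: preferred %s", rec.locus_id, rec.preferred)
    result = run_battery(retained, sorted(models), alpha=cfg.alpha,
                         seed=base_seed)
    (edir / "tests.json").write_text(json.dumps(result.to_dict(), indent=1))
    rows = ["locus_id\t" + "\t".join(f"outcome_{m}" for m in sorted(models))]
    for idx, rec in enumerate(retained):
        rows.append(rec.locus_id + "\t" + "\t".join(
            str(result.outcomes[m][idx]) for m in sorted(models)))
    (edir / "outcomes.tsv").write_text("\n".join(rows) + "\n")


def load_experiment(outdir: Path, records: list[GeneRecord] | None = None
                    ) -> list[GeneRecord]:
    """Reload retained records with their stored fits."""
    records = records if records is not None else load_records(outdir)
    edir = outdir / "experiment"
    retained_ids = (edir / "retained.txt").read_text().split()
    by_id = {r.locus_id: r for r in records}
    retained = []
    for locus_id in retained_ids:
        rec = by_id[locus_id]
        payload = json.loads((edir / "fits" / f"{locus_id}.json").read_text())
        rec.preferred = payload.pop("preferred")
        for key, fd in payload.items():
            m, t = key.split("|")
            rec.fits[(m, t)] = FittedModel(
                family=fd["family"], params=fd["params"],
                tree=PhyloTree.from_newick(fd["tree"], units="substitution"),
                lnL=fd["lnL"], start_lnLs=fd["start_lnLs"],
                converged=fd["converged"])
        retained.append(rec)
    return retained


# --------------------------------------------------------------------------
# stage 4: species trees
# --------------------------------------------------------------------------
def _gt_sets(retained: Sequence[GeneRecord]) -> dict[str, list[PhyloTree]]:
    sets: dict[str, list[PhyloTree]] = {
        "Est.ST.1": [], "Est.ST.2": [],
        "Min.Discord.ST": [], "Max.Discord.ST": [],
    }
    model_names = sorted({m for (m, _) in retained[0].fits})
    for m in model_names:
        sets[f"{m}.ST"] = []
    for rec in retained:
        sets["Est.ST.1"].append(rec.topologies[EST1_LABEL])
        sets["Est.ST.2"].append(rec.topologies[EST2_LABEL])
        sets["Min.Discord.ST"].append(
            rec.topologies[rec.distances.least_discordant])
        sets["Max.Discord.ST"].append(
            rec.topologies[rec.distances.most_discordant])
        for m in model_names:
            pref = rec.preferred.get(m)
            # the model's chosen GT among the two estimated candidates:
            # fall back to the better-lnL estimated GT when the reference
            # topology had the best lnL
            if pref in (EST1_LABEL, EST2_LABEL):
                sets[f"{m}.ST"].append(rec.topologies[pref])
            else:
                lnls = rec.lnls_for(m)
                best_est = max((EST1_LABEL, EST2_LABEL), key=lnls.get)
                sets[f"{m}.ST"].append(rec.topologies[best_est])
    return sets


def stage_speciestree(cfg: PipelineConfig, outdir: Path) -> None:
    st_true, outgroup, alns, _ = load_dataset(outdir)
    records = load_records(outdir)
    retained = load_experiment(outdir, records)
    sdir = outdir / "speciestree"
    sdir.mkdir(exist_ok=True)
    base_seed = cfg.seed + SEED_OFFSETS["speciestree"]

    sets = _gt_sets(retained)
    retained_ids = {r.locus_id for r in retained}
    independent = []
    for rec in records:
        if rec.locus_id not in retained_ids:
            independent.append(rec.topologies[EST1_LABEL])
            independent.append(rec.topologies[EST2_LABEL])

    # the reference ("concatenation-role") topology on the full taxon set
    ref_full = st_true
    estimates: dict[str, tuple[PhyloTree, int]] = {}
    for name, gts in sorted(sets.items()):
        tree, score = estimate_species_tree(gts, mode="auto")
        estimates[name] = (tree, score)
        (sdir / f"{name}.nwk").write_text(tree.to_newick() + "\n")
        log.info("estimated %s (quartet score %d)", name, score)

    # references for the composite scores, all trimmed to a common leaf set
    common = set(ref_full.taxa)
    for tree, _ in estimates.values():
        common &= tree.taxa
    concat_c = trim_to_common_taxa(ref_full, common)
    min_c = trim_to_common_taxa(estimates["Min.Discord.ST"][0], common)
    max_c = trim_to_common_taxa(estimates["Max.Discord.ST"][0], common)
    refs = (concat_c, min_c, max_c)
    # selected relationships: reference clades not found in the
    # maximal-discordance tree
    anchor = min(common)
    concat_r = root_on_outgroup(concat_c, anchor)
    max_r = root_on_outgroup(max_c, anchor)
    relationships = [set(s) for s in concat_r.unrooted_splits()
                     if not max_r.is_monophyletic(s)]
    # control nodes: clades of the true species tree (known by construction)
    st_rooted = root_on_outgroup(trim_to_common_taxa(st_true, common), anchor)
    controls = [set(s) for s in st_rooted.unrooted_splits()]

    reports: dict[str, SpeciesTreeReport] = {}
    rows1 = ["species_tree\tn_gene_trees\tquartet_score\tdistance_score"
             "\tselected_relationships"]
    rows2 = ["species_tree\tmean_support\tmean_split_frequency"
             "\tmean_rf_among_gts\tpredictive_mean\tpredictive_ci_low"
             "\tpredictive_ci_high\tcontrol_nodes"]
    for name, (tree, score) in sorted(estimates.items()):
        tree_c = trim_to_common_taxa(tree, common)
        rep = evaluate_species_tree(
            name, tree_c, sets[name], quartet_score=score, refs=refs,
            relationships=relationships,
            independent_gts=[trim_to_common_taxa(g, g.taxa & common)
                             for g in independent
                             if len(g.taxa & common) >= 4] or None,
            controls=controls, seed=base_seed)
        reports[name] = rep
        rows1.append(f"{name}\t{len(sets[name])}\t{score}"
                     f"\t{rep.distance_score:.4f}"
                     f"\t{rep.selected_relationships}")
        ci = rep.predictive_ci or (float("nan"), float("nan"))
        rows2.append(f"{name}\t{rep.mean_support:.4f}"
                     f"\t{rep.mean_split_frequency:.4f}"
                     f"\t{rep.mean_rf_among_gts:.4f}"
                     f"\t{rep.predictive_mean if rep.predictive_mean is not None else float('nan'):.4f}"
                     f"\t{ci[0]:.4f}\t{ci[1]:.4f}\t{rep.control_nodes}")
        branch_rows = ["split\tq1\tq2\tq3\tsupport\tcoalescent_length"
                       "\tgcf\tsplit_frequency"]
        for b in rep.branches:
            branch_rows.append(
                f"{'|'.join(sorted(b.split))}\t{b.q1:.4f}\t{b.q2:.4f}"
                f"\t{b.q3:.4f}\t{b.support:.4f}\t{b.coalescent_length:.4f}"
                f"\t{b.gcf if b.gcf is not None else 'NA'}"
                f"\t{b.split_frequency:.4f}")
        (sdir / f"{name}.branches.tsv").write_text(
            "\n".join(branch_rows) + "\n")
    (sdir / "table1.tsv").write_text("\n".join(rows1) + "\n")
    (sdir / "table2.tsv").write_text("\n".join(rows2) + "\n")
    (sdir / "reports.json").write_text(json.dumps(
        {k: v.to_dict() for k, v in reports.items()}, indent=1))


# --------------------------------------------------------------------------
# stage 5: anomaly scan
# --------------------------------------------------------------------------
FINAL_ST = "SelAC.ST"


def stage_anomaly(cfg: PipelineConfig, outdir: Path) -> None:
    sdir = outdir / "speciestree"
    adir = outdir / "anomaly"
    adir.mkdir(exist_ok=True)
    records = load_records(outdir)
    retained = load_experiment(outdir, records)
    name = FINAL_ST if (sdir / f"{FINAL_ST}.nwk").exists() else "Est.ST.1"
    st = PhyloTree.from_newick((sdir / f"{name}.nwk").read_text(),
                               rooted=False)
    gts = _gt_sets(retained)[name]
    metrics = branch_metrics(st, gts)
    lengths = {b.split: b.coalescent_length for b in metrics
               if np.isfinite(b.q1)}
    anchor = min(st.taxa)
    rooted = root_on_outgroup(st, anchor)
    report = detect_anomalous_pairs(rooted, lengths=lengths)
    report.difficult = difficult_nodes(metrics)
    rows = ["parent_split\tchild_split\tx\ty\ta_x\tanomalous"]
    for p in report.pairs:
        rows.append(f"{'|'.join(sorted(p.parent_split))}"
                    f"\t{'|'.join(sorted(p.child_split))}"
                    f"\t{p.x:.4f}\t{p.y:.4f}\t{p.a_x:.4f}\t{p.anomalous}")
    (adir / "pairs.tsv").write_text("\n".join(rows) + "\n")
    rows = ["split\tcoalescent_length\tgcf\tsplit_frequency\tsupport\tflagged"]
    for d in report.difficult:
        rows.append(f"{'|'.join(sorted(d.split))}\t{d.coalescent_length:.4f}"
                    f"\t{d.gcf if d.gcf is not None else 'NA'}"
                    f"\t{d.split_frequency:.4f}\t{d.support:.4f}\t{d.flagged}")
    (adir / "difficult.tsv").write_text("\n".join(rows) + "\n")
    summary = report.to_dict()
    summary["species_tree"] = name
    (adir / "summary.json").write_text(json.dumps(summary, indent=1))


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------
_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "genetrees": stage_genetrees,
    "experiment": stage_experiment,
    "speciestree": stage_speciestree,
    "anomaly": stage_anomaly,
}


def run_pipeline(cfg: PipelineConfig, outdir: str | Path,
                 resume: bool = False,
                 stages: Sequence[str] = STAGES) -> dict:
    """Run the pipeline stages in order, skipping completed stages when
    ``resume`` is set; returns the exit report (also written to
    report.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(json.dumps(cfg.to_dict(), indent=1))
    for stage in STAGES:
        if stage not in stages:
            continue
        if resume and _done(outdir, stage).exists():
            log.info("stage %s already complete; skipping", stage)
            continue
        log.info("running stage %s", stage)
        try:
            _STAGE_FUNCS[stage](cfg, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        _mark(outdir, stage)
    report = build_report(outdir)
    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    return report


def build_report(outdir: Path) -> dict:
    """Summarize the run from its on-disk artifacts."""
    outdir = Path(outdir)
    report: dict = {}
    dist_path = outdir / "genetrees" / "distances.tsv"
    if dist_path.exists():
        lines = dist_path.read_text().strip().splitlines()
        header = lines[0].split("\t")
        agree_col = header.index("metrics_agree")
        agree = [l.split("\t")[agree_col] == "True" for l in lines[1:]]
        report["n_loci"] = len(agree)
        report["n_metrics_agree"] = int(sum(agree))
        report["metrics_agree_fraction"] = float(np.mean(agree))
    tests_path = outdir / "experiment" / "tests.json"
    if tests_path.exists():
        report["experiment"] = json.loads(tests_path.read_text())
    t1 = outdir / "speciestree" / "table1.tsv"
    if t1.exists():
        rows = [l.split("\t") for l in t1.read_text().strip().splitlines()]
        report["species_trees"] = {
            r[0]: {"quartet_score": int(r[2]),
                   "distance_score": float(r[3]),
                   "selected_relationships": int(r[4])}
            for r in rows[1:]}
    a = outdir / "anomaly" / "summary.json"
    if a.exists():
        report["anomaly"] = json.loads(a.read_text())
    return report
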