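"""Stage orchestration: each stage reads the previous stage's files from a
run directory, writes its own, and appends a manifest entry (config
snapshot, file checksums, row counts, seed), so reruns are reproducible
and stage outputs are consumable independently."""

from __future__ import annotations

import hashlib
import json
import time
from collections import Counter, defaultdict
from pathlib import Path

import numpy as np
import pandas as pd

from duplidate import __version__
from duplidate import io as dio
from duplidate.alignprep import Alignment, backtranslate_alignment, filter_family_alignment
from duplidate.config import PipelineConfig
from duplidate.enrich import fisher_enrichment
from duplidate.fourdtv import PairStatus, family_pairwise_4dtv
from duplidate.mixture import fit_lognormal_mixture, histogram_4dtv
from duplidate.reconcile import (
    SpeciesTreeIndex,
    count_duplications_per_branch,
    lca_map,
    representative_pair_selector,
    tag_duplications,
)
from duplidate.simulate import (
    SimulationConfig,
    family_table,
    simulate_families,
    simulate_genomes,
    truth_table,
)
from duplidate.synteny import (
    GenomeGeneOrder,
    SyntenyLabel,
    classify_pair_across_genomes,
    synteny_summary,
)

STAGES = ("simulate", "prep", "reconcile", "fourdtv", "synteny", "density", "enrich")


class StageError(RuntimeError):
    """A stage cannot run; the message names the producing stage to run first."""


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise StageError(f"missing {path.name}: run the `{producer}` stage first")
    return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _append_manifest(outdir: Path, stage: str, files: list[Path],
                     rows: dict, config: dict, seed: int | None) -> None:
    manifest_path = outdir / "manifest.json"
    entries = json.loads(manifest_path.read_text()) if manifest_path.exists() else []
    entries = [e for e in entries if e["stage"] != stage]
    entries.append({
        "stage": stage,
        "version": __version__,
        "seed": seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": config,
        "row_counts": rows,
        "files": {p.name: _sha256(p) for p in sorted(files)},
    })
    manifest_path.write_text(json.dumps(entries, indent=2) + "\n")


# ---------------------------------------------------------------- simulate

def stage_simulate(sim_config: SimulationConfig, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aln_dir = outdir / "alignments"
    aln_dir.mkdir(exist_ok=True)
    rng = np.random.default_rng(sim_config.seed)
    species_root, families = simulate_families(sim_config, rng)
    genomes, positions = simulate_genomes(sim_config, species_root, families, rng)

    (outdir / "species.nwk").write_text(_snode_newick(species_root) + "\n")
    (outdir / "gene_trees.nwk").write_text(
        "".join(f.newick + "\n" for f in families)
    )
    fam_tab = family_table(families)
    dio.write_table(fam_tab, outdir / "families.tsv")
    dio.write_table(positions, outdir / "positions.tsv")
    truth = truth_table(families)
    dio.write_table(truth, outdir / "truth_pairs.tsv")
    for fam in families:
        dio.write_fasta(fam.protein_alignment().rows, aln_dir / f"{fam.family_id}.prot.fasta")
        dio.write_fasta(sorted(fam.sequences.items()), aln_dir / f"{fam.family_id}.cds.fasta")
    annotations = _simulate_annotations(families, rng)
    dio.write_table(annotations, outdir / "annotations.tsv")

    files = [outdir / n for n in
             ("species.nwk", "gene_trees.nwk", "families.tsv", "positions.tsv",
              "truth_pairs.tsv", "annotations.tsv")]
    rows = {"families": len(families), "genes": len(fam_tab),
            "truth_pairs": len(truth), "positions": len(positions)}
    cfg = {k: (v if not isinstance(v, list) else [vars(e) for e in v])
           for k, v in vars(sim_config).items()}
    cfg["wgd_events"] = [vars(e) for e in sim_config.wgd_events]
    _append_manifest(outdir, "simulate", files, rows, cfg, sim_config.seed)
    return rows


def _snode_newick(root) -> str:
    def render(node, parent_age):
        length = parent_age - node.age
        if node.is_leaf():
            return f"{next(iter(node.clade))}:{length:.8g}"
        inner = ",".join(render(c, node.age) for c in node.children)
        return f"({inner}):{length:.8g}"

    inner = ",".join(render(c, root.age) for c in root.children)
    return f"({inner});"


def _simulate_annotations(families, rng, n_terms: int = 50,
                          terms_per_gene: int = 3) -> pd.DataFrame:
    """Random term annotations (null with respect to duplication status),
    so enrichment runs end-to-end and behaves like a negative control."""
    rows = []
    for fam in families:
        for gid in sorted(fam.gene_species):
            for t in sorted(rng.choice(n_terms, size=terms_per_gene, replace=False)):
                rows.append((gid, f"T{t:03d}"))
    return pd.DataFrame(rows, columns=["gene_id", "term_id"])


# ---------------------------------------------------------------- prep

def stage_prep(outdir: str | Path, config: PipelineConfig) -> dict:
    outdir = Path(outdir)
    aln_dir = _require(outdir / "alignments", "simulate")
    codon_dir = outdir / "codon_alignments"
    codon_dir.mkdir(exist_ok=True)
    report_rows = []
    n_fam = n_kept = 0
    for prot_path in sorted(aln_dir.glob("*.prot.fasta")):
        fam_id = prot_path.name.removesuffix(".prot.fasta")
        n_fam += 1
        prot = Alignment(fam_id, dio.read_fasta(prot_path))
        cds = dict(dio.read_fasta(aln_dir / f"{fam_id}.cds.fasta"))
        cds_ungapped = {g: s.replace("-", "") for g, s in cds.items()}
        filtered, removals = filter_family_alignment(prot, cds_ungapped, config)
        for gid, reason in removals:
            report_rows.append((fam_id, gid, reason))
        if filtered is None:
            report_rows.append((fam_id, "*", "family_discarded"))
            continue
        codon = backtranslate_alignment(filtered, cds_ungapped)
        dio.write_fasta(codon.rows, codon_dir / f"{fam_id}.codon.fasta")
        n_kept += 1
    report = pd.DataFrame(report_rows, columns=["family_id", "gene_id", "reason"])
    dio.write_table(report, outdir / "prep_report.tsv")
    rows = {"families_in": n_fam, "families_out": n_kept, "removals": len(report)}
    _append_manifest(outdir, "prep", [outdir / "prep_report.tsv"], rows,
                     config.asdict(), config.rng_seed)
    return rows


# ---------------------------------------------------------------- reconcile

def stage_reconcile(outdir: str | Path, config: PipelineConfig,
                    representative_pairs: bool = False) -> dict:
    """Tag duplications per gene tree.  With ``representative_pairs`` each
    event emits only the cross pair with the most qualifying fourfold
    sites (requires the codon alignments from `prep`)."""
    outdir = Path(outdir)
    species = dio.read_newick(_require(outdir / "species.nwk", "simulate"))
    index = SpeciesTreeIndex(species)
    forest = dio.read_newick_forest(_require(outdir / "gene_trees.nwk", "simulate"))
    fam_tab = dio.read_family_table(_require(outdir / "families.tsv", "simulate"))
    gene_to_species = dict(zip(fam_tab["gene_id"], fam_tab["species_id"]))
    gene_to_family = dict(zip(fam_tab["gene_id"], fam_tab["family_id"]))
    codon_dir = _require(outdir / "codon_alignments", "prep") if representative_pairs else None

    rows = []
    all_events = []
    for tree in forest:
        leaves = [l.taxon.label for l in tree.leaf_node_iter()]
        fam_id = gene_to_family.get(leaves[0])
        if fam_id is None:
            raise StageError(f"gene {leaves[0]!r} absent from families.tsv")
        rec = lca_map(tree, index, gene_to_species)
        selector = None
        if codon_dir is not None:
            path = codon_dir / f"{fam_id}.codon.fasta"
            if path.exists():
                selector = representative_pair_selector(dict(dio.read_fasta(path)))
        for ev in tag_duplications(fam_id, rec, index, pair_selector=selector):
            all_events.append(ev)
            rows.append((ev.family_id, ev.node_id, ev.branch,
                         ";".join(f"{a}|{b}" for a, b in ev.pairs)))
    events = pd.DataFrame(rows, columns=["family_id", "node_id", "branch", "pairs"])
    events = events.sort_values(["family_id", "node_id"]).reset_index(drop=True)
    dio.write_table(events, outdir / "events.tsv")
    counts = count_duplications_per_branch(all_events, index)
    dio.write_table(counts, outdir / "branch_counts.tsv")
    rows_n = {"gene_trees": len(forest), "events": len(events)}
    _append_manifest(outdir, "reconcile",
                     [outdir / "events.tsv", outdir / "branch_counts.tsv"],
                     rows_n, config.asdict(), config.rng_seed)
    return rows_n


def read_events(outdir: Path) -> pd.DataFrame:
    events = pd.read_csv(_require(outdir / "events.tsv", "reconcile"),
                         sep="\t", dtype=str)
    events["pairs"] = events["pairs"].fillna("")
    return events


def event_pairs(events: pd.DataFrame):
    """Yield (family_id, branch, [(gene_a, gene_b), ...]) per event row."""
    for _, row in events.iterrows():
        pairs = [tuple(p.split("|")) for p in row["pairs"].split(";") if p]
        yield row["family_id"], row["branch"], pairs


# ---------------------------------------------------------------- fourdtv

def stage_fourdtv(outdir: str | Path, config: PipelineConfig) -> dict:
    outdir = Path(outdir)
    codon_dir = _require(outdir / "codon_alignments", "prep")
    events = read_events(outdir)
    rows = []
    for fam_id, branch, pairs in event_pairs(events):
        path = codon_dir / f"{fam_id}.codon.fasta"
        if not path.exists():
            continue  # family dropped by prep filters
        aln = Alignment(fam_id, dio.read_fasta(path))
        present = set(aln.ids())
        usable = [p for p in pairs if p[0] in present and p[1] in present]
        for d in family_pairwise_4dtv(aln, usable, min_sites=config.min_4d_sites):
            rows.append((fam_id, branch, d.gene_a, d.gene_b, d.n_4d_sites,
                         d.n_transversions,
                         "" if d.raw_4dtv is None else f"{d.raw_4dtv:.8g}",
                         "" if d.corrected_4dtv is None else f"{d.corrected_4dtv:.8g}",
                         d.status.value))
    table = pd.DataFrame(rows, columns=[
        "family_id", "branch", "gene_a", "gene_b", "n_4d_sites",
        "n_transversions", "raw_4dtv", "corrected_4dtv", "status"])
    dio.write_table(table, outdir / "fourdtv.tsv")
    n = {"pairs": len(table),
         "ok": int((table["status"] == "OK").sum()) if len(table) else 0}
    _append_manifest(outdir, "fourdtv", [outdir / "fourdtv.tsv"], n,
                     config.asdict(), config.rng_seed)
    return n


# ---------------------------------------------------------------- synteny

def stage_synteny(outdir: str | Path, config: PipelineConfig) -> dict:
    outdir = Path(outdir)
    positions = dio.read_position_table(_require(outdir / "positions.tsv", "simulate"))
    fam_tab = dio.read_family_table(_require(outdir / "families.tsv", "simulate"))
    family_of = dict(zip(fam_tab["gene_id"], fam_tab["family_id"]))
    genomes = [
        GenomeGeneOrder.from_position_table(positions, g, family_of)
        for g in sorted(positions["genome_id"].unique())
    ]
    events = read_events(outdir)
    pair_rows = []
    labels_by_branch: dict[str, list[SyntenyLabel]] = defaultdict(list)
    for fam_id, branch, pairs in event_pairs(events):
        event_votes = []
        for a, b in pairs:
            consensus, votes = classify_pair_across_genomes(a, b, genomes, config)
            pair_rows.append((
                fam_id, branch, a, b, consensus.value,
                ";".join(f"{g}={v.value}" for g, v in sorted(votes.items())
                         if v != SyntenyLabel.NO_INFO),
            ))
            event_votes.append(consensus)
        informative = {v for v in event_votes if v != SyntenyLabel.NO_INFO}
        if not informative:
            event_label = SyntenyLabel.NO_INFO
        elif len(informative) == 1:
            event_label = next(iter(informative))
        else:
            event_label = SyntenyLabel.CONFLICTING
        labels_by_branch[branch].append(event_label)
    pair_table = pd.DataFrame(pair_rows, columns=[
        "family_id", "branch", "gene_a", "gene_b", "consensus", "votes"])
    dio.write_table(pair_table, outdir / "synteny_pairs.tsv")
    summary = synteny_summary(dict(labels_by_branch))
    dio.write_table(summary, outdir / "synteny_branch_summary.tsv")
    n = {"pairs": len(pair_table), "branches": len(summary)}
    _append_manifest(outdir, "synteny",
                     [outdir / "synteny_pairs.tsv", outdir / "synteny_branch_summary.tsv"],
                     n, config.asdict(), config.rng_seed)
    return n


# ---------------------------------------------------------------- density

def stage_density(outdir: str | Path, config: PipelineConfig) -> dict:
    outdir = Path(outdir)
    table = pd.read_csv(_require(outdir / "fourdtv.tsv", "fourdtv"), sep="\t")
    ok = table[table["status"] == PairStatus.OK.value]
    values = ok["corrected_4dtv"].astype(float)
    values = values[values > 0]
    fit = fit_lognormal_mixture(
        values,
        k_candidates=config.mixture_k_candidates,
        seed=config.rng_seed,
        n_init=config.mixture_n_init,
        grid_min=config.density_grid_min,
        grid_max=config.density_grid_max,
        grid_step=config.density_grid_step,
    )
    comp = pd.DataFrame({
        "component": range(1, fit.k + 1),
        "weight": fit.weights,
        "log_mean": fit.means,
        "log_sd": fit.sigmas,
        "mode": fit.component_modes,
    })
    dio.write_table(comp, outdir / "mixture_components.tsv")
    dio.write_table(pd.DataFrame({"maximum_4dtv": fit.maxima}),
                    outdir / "density_maxima.tsv")
    hist = histogram_4dtv(values, config)
    dio.write_table(pd.DataFrame({
        "bin_left": hist["bin_left"], "bin_right": hist["bin_right"],
        "count": hist["count"]}), outdir / "histogram.tsv")

    # Fig 4 analogue: per-branch counts + synteny percentages + 4dTv medians
    counts = pd.read_csv(_require(outdir / "branch_counts.tsv", "reconcile"), sep="\t")
    med = ok.assign(corr=ok["corrected_4dtv"].astype(float)) \
            .groupby("branch")["corr"].median().rename("median_corrected_4dtv")
    joined = counts.merge(med, on="branch", how="left")
    syn_path = outdir / "synteny_branch_summary.tsv"
    if syn_path.exists():
        syn = pd.read_csv(syn_path, sep="\t")
        joined = joined.merge(syn, on="branch", how="left")
    dio.write_table(joined, outdir / "branch_summary.tsv")

    n = {"values": int(len(values)), "k": fit.k,
         "maxima": [round(m, 4) for m in fit.maxima]}
    _append_manifest(outdir, "density",
                     [outdir / f for f in ("mixture_components.tsv",
                                           "density_maxima.tsv", "histogram.tsv",
                                           "branch_summary.tsv")],
                     n, config.asdict(), config.rng_seed)
    return n


# ---------------------------------------------------------------- enrich

def stage_enrich(outdir: str | Path, config: PipelineConfig,
                 branch: str | None = None) -> dict:
    outdir = Path(outdir)
    annotation = dio.read_annotation_table(_require(outdir / "annotations.tsv", "simulate"))
    fam_tab = dio.read_family_table(_require(outdir / "families.tsv", "simulate"))
    events = read_events(outdir)
    background = set(fam_tab["gene_id"])
    if branch is None:
        branch_counts = Counter(events["branch"])
        if not branch_counts:
            dio.write_table(pd.DataFrame(
                columns=["term_id", "annotated", "significant", "expected",
                         "p_value", "fdr"]), outdir / "enrichment.tsv")
            _append_manifest(outdir, "enrich", [outdir / "enrichment.tsv"],
                             {"terms": 0}, config.asdict(), config.rng_seed)
            return {"terms": 0}
        branch = branch_counts.most_common(1)[0][0]
    foreground = set()
    for fam_id, ev_branch, pairs in event_pairs(events):
        if ev_branch == branch:
            for a, b in pairs:
                foreground.update((a, b))
    foreground &= background
    result = fisher_enrichment(annotation, foreground, background)
    dio.write_table(result, outdir / "enrichment.tsv")
    n = {"terms": len(result), "branch": branch, "foreground": len(foreground)}
    _append_manifest(outdir, "enrich", [outdir / "enrichment.tsv"], n,
                     config.asdict(), config.rng_seed)
    return n


# ---------------------------------------------------------------- driver

def run_stage(name: str, outdir: str | Path, config: PipelineConfig,
              sim_config: SimulationConfig | None = None,
              representative_pairs: bool = False) -> dict:
    if name == "simulate":
        if sim_config is None:
            raise StageError("`simulate` needs a simulation config")
        return stage_simulate(sim_config, outdir)
    if name == "prep":
        return stage_prep(outdir, config)
    if name == "reconcile":
        return stage_reconcile(outdir, config,
                               representative_pairs=representative_pairs)
    if name == "fourdtv":
        return stage_fourdtv(outdir, config)
    if name == "synteny":
        return stage_synteny(outdir, config)
    if name == "density":
        return stage_density(outdir, config)
    if name == "enrich":
        return stage_enrich(outdir, config)
    if name == "all":
        out = {}
        for stage in ("prep", "reconcile", "fourdtv", "synteny", "density", "enrich"):
            out[stage] = run_stage(stage, outdir, config,
                                   representative_pairs=representative_pairs)
        return out
    raise StageError(f"unknown stage {name!r}; choose from {STAGES + ('all',)}")
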