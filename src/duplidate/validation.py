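"""Validation experiments with known ground truth.

Each function runs one planted-truth experiment end to end through the
package and returns the measured quantities (accuracies, recovered modes,
error rates).  The naive reference implementations used as oracles here
are written independently of the production code paths: the 4dTv recount
re-derives the fourfold-degenerate families from the genetic code and
scans columns one by one, and the reconciliation oracle finds each
mapping by scanning every species-tree clade.
"""

from __future__ import annotations

import math
from math import comb

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from duplidate import io as dio
from duplidate.config import PipelineConfig
from duplidate.enrich import fisher_enrichment
from duplidate.fourdtv import four_dtv
from duplidate.mixture import fit_lognormal_mixture
from duplidate.reconcile import SpeciesTreeIndex, lca_map, tag_duplications
from duplidate.simulate import (
    GNode,
    SimulationConfig,
    WgdEvent,
    evolve_fourfold_sites,
    simulate_families,
    simulate_genomes,
)
from duplidate.synteny import SyntenyLabel, classify_pair_across_genomes

LADDER = "(((A:0.2,B:0.2):0.2,C:0.4):0.5,D:0.9);"

_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]


# ------------------------------------------------------------ oracles

def naive_fourfold_prefixes() -> set[str]:
    out = set()
    for a in "ACGT":
        for b in "ACGT":
            aas = {str(Seq(a + b + c).translate()) for c in "ACGT"}
            if len(aas) == 1 and "*" not in aas:
                out.add(a + b)
    return out


def naive_pair_counts(row_a: str, row_b: str) -> tuple[int, int]:
    fourfold = naive_fourfold_prefixes()
    purine = {"A": True, "G": True, "C": False, "T": False}
    sites = tv = 0
    for i in range(0, len(row_a), 3):
        ca, cb = row_a[i:i + 3], row_b[i:i + 3]
        if any(ch not in "ACGT" for ch in ca + cb):
            continue
        if ca[:2] != cb[:2] or ca[:2] not in fourfold:
            continue
        sites += 1
        if purine[ca[2]] != purine[cb[2]]:
            tv += 1
    return sites, tv


def naive_reconcile(gene_tree, species_tree, gene_to_species):
    clades = {}
    for node in species_tree.postorder_node_iter():
        if node.is_leaf():
            clades[node] = frozenset({node.taxon.label})
        else:
            clades[node] = frozenset().union(*(clades[c] for c in node.child_nodes()))
    mapping, labels = {}, {}
    for node in gene_tree.postorder_node_iter():
        species = frozenset(gene_to_species[l.taxon.label] for l in node.leaf_iter())
        candidates = [n for n, c in clades.items() if species <= c]
        mapping[node] = min(candidates, key=lambda n: len(clades[n]))
        if not node.is_leaf():
            labels[node] = (
                "duplication"
                if any(mapping[c] is mapping[node] for c in node.child_nodes())
                else "speciation"
            )
    return mapping, labels


def _random_codon_row(rng: np.random.Generator, n_codons: int) -> str:
    out = []
    for _ in range(n_codons):
        u = rng.random()
        if u < 0.05:
            out.append("---")
        elif u < 0.07:
            codon = list(_CODONS[rng.integers(64)])
            codon[rng.integers(3)] = "N"
            out.append("".join(codon))
        else:
            out.append(_CODONS[rng.integers(64)])
    return "".join(out)


def _random_topology(rng: np.random.Generator, labels: list[str]) -> str:
    def build(names):
        if len(names) == 1:
            return names[0]
        k = int(rng.integers(1, len(names)))
        return f"({build(names[:k])},{build(names[k:])})"

    shuffled = list(labels)
    rng.shuffle(shuffled)
    return build(shuffled) + ";"


# ------------------------------------------------------------ experiments

def fourdtv_oracle_check(seed: int, n_pairs: int = 1000, n_codons: int = 40) -> dict:
    """Agreement of 4dTv counts with the naive per-column recount, the
    worst-case error of the correction formula, and symmetry."""
    rng = np.random.default_rng(seed)
    agree = 0
    max_err = 0.0
    symmetric = True
    for _ in range(n_pairs):
        a = _random_codon_row(rng, n_codons)
        b = _random_codon_row(rng, n_codons)
        d = four_dtv("a", a, "b", b, min_sites=1)
        rev = four_dtv("a", b, "b", a, min_sites=1)
        symmetric &= (d.n_4d_sites, d.n_transversions) == (rev.n_4d_sites, rev.n_transversions)
        if (d.n_4d_sites, d.n_transversions) == naive_pair_counts(a, b):
            agree += 1
        if d.raw_4dtv is not None and d.raw_4dtv < 0.5:
            err = abs(d.corrected_4dtv - (-math.log(1 - 2 * d.raw_4dtv) / 2))
            max_err = max(max_err, err)
    return {
        "agreement_pct": 100.0 * agree / n_pairs,
        "max_correction_abs_err": max_err,
        "symmetric": symmetric,
        "n": n_pairs,
    }


def jc_recovery(seed: int, n_pairs: int = 200, n_sites: int = 500,
                t_each: float = 0.3, mu: float = 1.0) -> dict:
    """Mean corrected 4dTv of Jukes-Cantor-simulated pairs against the
    closed form 2*mu*(2t)/3 (here 0.4 with the defaults)."""
    rng = np.random.default_rng(seed)
    corrected = []
    for _ in range(n_pairs):
        root = GNode(t_each, [GNode(0.0, name="a"), GNode(0.0, name="b")])
        seqs = evolve_fourfold_sites(root, mu, n_sites, rng)
        d = four_dtv("a", seqs["a"], "b", seqs["b"])
        if d.corrected_4dtv is not None:
            corrected.append(d.corrected_4dtv)
    corrected = np.asarray(corrected)
    return {
        "mean_corrected": float(corrected.mean()),
        "expected": 2 * mu * 2 * t_each / 3,
        "se": float(corrected.std(ddof=1) / math.sqrt(len(corrected))),
        "n": len(corrected),
    }


def reconciliation_oracle_check(seed: int, n_cases: int = 500,
                                max_leaves: int = 10) -> dict:
    """Agreement of LCA reconciliation (mappings + labels) with the naive
    all-clades oracle on random gene/species tree pairs."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_cases):
        n_sp = int(rng.integers(2, max_leaves + 1))
        species = [f"S{i}" for i in range(n_sp)]
        sp_tree = dio.read_newick(_random_topology(rng, species))
        idx = SpeciesTreeIndex(sp_tree)
        n_genes = int(rng.integers(2, 9))
        g2s = {f"g{i}": species[rng.integers(n_sp)] for i in range(n_genes)}
        gene_tree = dio.read_newick(_random_topology(rng, sorted(g2s)))
        rec = lca_map(gene_tree, idx, g2s)
        bmap, blabels = naive_reconcile(gene_tree, idx.tree, g2s)
        ok = all(rec.mapping[n] is bmap[n] for n in gene_tree.postorder_node_iter())
        ok &= rec.labels == blabels
        agree += ok
    return {"agreement_pct": 100.0 * agree / n_cases, "n": n_cases}


def _reconcile_all(species_newick: str, families) -> list:
    idx = SpeciesTreeIndex(dio.read_newick(species_newick))
    events = []
    for fam in families:
        rec = lca_map(dio.read_newick(fam.newick), idx, fam.gene_species)
        events.extend(tag_duplications(fam.family_id, rec, idx))
    return events


def planted_wgd_assignment(seed: int, n_families: int = 200) -> dict:
    """Branch-assignment accuracy for an instantly rediploidized WGD
    (onset offset 0) planted on one internal branch."""
    cfg = SimulationConfig(
        species_newick=LADDER, n_families=n_families,
        wgd_events=[WgdEvent(branch="A+B+C", retention=1.0, age=0.7)],
        n_sites=30, seed=seed)
    _, families = simulate_families(cfg)
    events = _reconcile_all(LADDER, families)
    correct = sum(e.branch == "A+B+C" for e in events)
    return {"accuracy_pct": 100.0 * correct / len(events), "n": len(events)}


def delayed_onset_leakage(seed: int, n_families: int = 100) -> dict:
    """With divergence onset postdating the next speciation, duplications
    are assigned to descendant branches (the leakage artefact)."""
    newick = "((A:1.0,B:1.0):1.0,C:2.0);"
    cfg = SimulationConfig(
        species_newick=newick, n_families=n_families,
        wgd_events=[WgdEvent(branch="A+B", retention=1.0, age=1.5,
                             onset_offset=0.8)],
        n_sites=30, seed=seed)
    _, families = simulate_families(cfg)
    events = _reconcile_all(newick, families)
    descendant = sum(e.branch in ("A", "B") for e in events)
    return {"descendant_pct": 100.0 * descendant / len(events), "n": len(events)}


def synteny_recovery(seed: int, gene_loss_frac: float = 0.0,
                     shuffle_frac: float = 0.0, n_pairs: int = 500,
                     n_families: int = 1000) -> dict:
    """Recovery of planted synteny labels from simulated genomes.

    Evaluates within-species truth pairs (the pairs a single genome can
    vote on): overall label accuracy on all pair types, SOME_SYNTENY
    recovery on the WGD pairs, and invariance under scaffold reversal.
    """
    cfg = SimulationConfig(
        species_newick=LADDER, n_families=n_families,
        wgd_events=[WgdEvent(branch="A+B", retention=0.55, age=0.3)],
        tandem_rate=0.05, n_sites=6, scaffold_size=60,
        gene_loss_frac=gene_loss_frac, shuffle_frac=shuffle_frac, seed=seed)
    root, families = simulate_families(cfg)
    genomes, _ = simulate_genomes(cfg, root, families)
    glist = list(genomes.values())
    reversed_glist = [
        type(g)(g.genome_id,
                {s: list(reversed(genes)) for s, genes in g.scaffolds.items()},
                g.family_of)
        for g in glist
    ]
    pcfg = PipelineConfig()
    pairs = [
        (fam, t) for fam in families for t in fam.truth_pairs
        if fam.gene_species[t.gene_a] == fam.gene_species[t.gene_b]
    ][:n_pairs]
    n_correct = n_some = n_some_correct = n_invariant = 0
    for fam, t in pairs:
        consensus, _ = classify_pair_across_genomes(t.gene_a, t.gene_b, glist, pcfg)
        rev_consensus, _ = classify_pair_across_genomes(
            t.gene_a, t.gene_b, reversed_glist, pcfg)
        n_invariant += consensus is rev_consensus
        n_correct += consensus.value == t.synteny_truth
        if t.synteny_truth == SyntenyLabel.SOME_SYNTENY.value:
            n_some += 1
            n_some_correct += consensus is SyntenyLabel.SOME_SYNTENY
    n = len(pairs)
    return {
        "overall_accuracy_pct": 100.0 * n_correct / n,
        "some_synteny_recovery_pct": 100.0 * n_some_correct / n_some,
        "reversal_invariance_pct": 100.0 * n_invariant / n,
        "n": n,
        "n_some": n_some,
    }


def mixture_selection(seed: int, n_seeds: int = 50, n_per_comp: int = 1000,
                      mode_low: float = 0.1, mode_high: float = 0.7,
                      sigma: float = 0.1) -> dict:
    """BIC component-count selection and mode recovery over repeated
    two-component lognormal simulations."""
    k2 = 0
    rel_errs = []
    integral = None
    for i in range(n_seeds):
        rng = np.random.default_rng(seed + i)
        values = np.concatenate([
            np.exp(rng.normal(np.log(mode_low), sigma, n_per_comp)),
            np.exp(rng.normal(np.log(mode_high), sigma, n_per_comp)),
        ])
        fit = fit_lognormal_mixture(values, k_candidates=(1, 2, 3, 4), seed=seed + i)
        if fit.k == 2:
            k2 += 1
            low, high = fit.maxima[0], fit.maxima[-1]
            rel_errs.append(abs(low - mode_low) / mode_low)
            rel_errs.append(abs(high - mode_high) / mode_high)
        if integral is None:
            grid = np.linspace(1e-4, 5.0, 20001)
            integral = float(np.trapezoid(fit.pdf(grid), grid))
    return {
        "k2_selected_pct": 100.0 * k2 / n_seeds,
        "max_mode_rel_err": float(max(rel_errs)) if rel_errs else float("nan"),
        "density_integral": integral,
        "n_seeds": n_seeds,
    }


def null_fdr_simulation(seed: int, n_replicates: int = 100, n_terms: int = 200,
                        n_genes: int = 1000, fg_size: int = 100) -> dict:
    """False-positive control: terms assigned independently of the
    foreground; mean fraction of terms with FDR < 0.05."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    rates = []
    for _ in range(n_replicates):
        rows = []
        for t in range(n_terms):
            size = int(rng.integers(10, 100))
            members = rng.choice(n_genes, size=size, replace=False)
            rows.extend((genes[m], f"T{t:03d}") for m in members)
        annotation = pd.DataFrame(rows, columns=["gene_id", "term_id"])
        fg = {genes[i] for i in rng.choice(n_genes, size=fg_size, replace=False)}
        table = fisher_enrichment(annotation, fg, set(genes))
        rates.append(float((table["fdr"] < 0.05).mean()))
    return {"mean_positive_rate": float(np.mean(rates)), "n": n_replicates}


def fisher_oracle_check(seed: int, n_tables: int = 1000) -> dict:
    """Fisher p against explicit binomial-coefficient tail sums on random
    2x2 tables with margins up to 200."""
    from duplidate.enrich import fisher_p

    rng = np.random.default_rng(seed)
    max_err = 0.0
    for _ in range(n_tables):
        bg = int(rng.integers(10, 201))
        fg = int(rng.integers(1, bg))
        ann = int(rng.integers(1, bg))
        sig = int(rng.integers(0, min(fg, ann) + 1))
        total = comb(bg, fg)
        brute = sum(
            comb(ann, k) * comb(bg - ann, fg - k)
            for k in range(sig, min(ann, fg) + 1)
        ) / total
        max_err = max(max_err, abs(fisher_p(sig, fg, ann, bg) - brute))
    return {"max_abs_err": max_err, "n": n_tables}


def two_event_scenario(seed: int, n_families: int = 300, n_sites: int = 500) -> SimulationConfig:
    """The standard two-event study scenario: an older duplication burst
    on the basal internal branch (expected corrected 4dTv 0.75) and a
    younger one on a later branch (expected 0.4)."""
    return SimulationConfig(
        species_newick=LADDER,
        n_families=n_families,
        wgd_events=[
            WgdEvent(branch="A+B+C", retention=0.45, age=0.7, onset_offset=0.1375),
            WgdEvent(branch="A+B", retention=0.8, age=0.35, onset_offset=0.05),
        ],
        mu=1.0, n_sites=n_sites, gene_loss_frac=0.1, shuffle_frac=0.05,
        scaffold_size=80, seed=seed)


def end_to_end(seed: int, outdir, n_families: int = 300) -> dict:
    """Run simulate + the full pipeline on the two-event scenario and
    report the recovered density maxima and branch assignments."""
    from duplidate.pipeline import run_stage

    sim = two_event_scenario(seed, n_families=n_families)
    pcfg = PipelineConfig(rng_seed=seed)
    run_stage("simulate", outdir, pcfg, sim_config=sim)
    run_stage("all", outdir, pcfg)
    from pathlib import Path

    out = Path(outdir)
    maxima = pd.read_csv(out / "density_maxima.tsv", sep="\t")["maximum_4dtv"].tolist()
    events = pd.read_csv(out / "events.tsv", sep="\t")
    truth = pd.read_csv(out / "truth_pairs.tsv", sep="\t")
    fourdtv = pd.read_csv(out / "fourdtv.tsv", sep="\t")
    per_branch = (
        fourdtv[fourdtv["status"] == "OK"]
        .groupby("branch")["corrected_4dtv"].median().to_dict()
    )
    return {
        "maxima": maxima,
        "n_events": len(events),
        "n_truth_pairs": len(truth),
        "median_4dtv_by_branch": per_branch,
        "n_values": int((fourdtv["status"] == "OK").sum()),
    }
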