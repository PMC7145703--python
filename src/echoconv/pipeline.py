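"""End-to-end orchestration: simulate -> filter -> reconstruct -> converge ->
select -> control-stats, with one seed, a manifest, and deterministic TSVs.

All randomness flows from the single config seed through named substreams
(one per gene and stage), so reruns with the same config produce
byte-identical outputs and genes are reproducible independently of batch
order.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from echoconv import study
from echoconv.align import FilterPolicy, filter_alignment, filter_report_rows, translate, write_fasta
from echoconv.controls import (
    METRICS,
    PairedCountTable,
    PairedRow,
    adaptive_overlap,
    t_test_report,
    table_rows,
)
from echoconv.convergence import calls_rows, classify_pair, summarize_pairs
from echoconv.phylo import mark_foreground, write_newick
from echoconv.reconstruct import default_model, fit_branch_lengths, reconstruct_marginal, reconstruction_rows
from echoconv.selection import results_rows, scan_genes
from echoconv.simulate import (
    SiteClassParams,
    inject_convergence,
    make_study_fixture,
    protein_view,
    simulate_codon_alignment,
)

log = logging.getLogger("echoconv")


@dataclass
class RunConfig:
    """One pipeline run: synthetic inputs, model thresholds, outputs.

    Thresholds default to the study values: BEB posterior 0.90, FDR 0.05,
    minimum CDS length 150 nt.
    """

    seed: int = 1
    output_dir: str = "echoconv_run"
    n_genes: int = 12
    n_sites: int = 120
    # simulation ground truth
    n_selected_genes: int = 2
    selection_foreground: str = "CF+FM"
    omega2: float = 6.0
    n_parallel_injected: int = 2
    inject_pair: tuple[str, str] = ("CF", "FM")
    params: dict = field(default_factory=dict)  # SiteClassParams overrides
    # analysis settings
    foreground_configs: tuple[str, ...] = ("CF", "CF+FM")
    n_starts: int = 2
    fit_asr_lengths: bool = False
    beb_threshold: float = 0.90
    fdr_threshold: float = 0.05
    min_cds_nt: int = 150

    def __post_init__(self):
        if not (0.0 < self.beb_threshold < 1.0 and 0.0 < self.fdr_threshold < 1.0):
            raise ValueError("thresholds must lie in (0, 1)")
        from echoconv.phylo import FOREGROUND_CONFIGS
        bad = [c for c in list(self.foreground_configs) + [self.selection_foreground]
               if c not in FOREGROUND_CONFIGS]
        if bad:
            raise ValueError(f"unknown foreground configuration(s): {bad}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "inject_pair" in data:
            data["inject_pair"] = tuple(data["inject_pair"])
        if "foreground_configs" in data:
            data["foreground_configs"] = tuple(data["foreground_configs"])
        return cls(**data)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


def _write_tsv(rows: list[dict], path: str, columns: list[str] | None = None) -> None:
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, sep="\t", index=False)


def gene_rng_seed(seed: int, gene_index: int) -> list[int]:
    """Named substream: [root seed, gene counter] feeds default_rng."""
    return [int(seed) % (2 ** 31), int(gene_index)]


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns (and writes) the manifest."""
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    handler = logging.FileHandler(os.path.join(out, "run.log"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest: dict = {"seed": config.seed, "stages": {}, "checksums": {}}
    outputs: list[str] = []

    try:
        # -- stage 1: simulate ------------------------------------------------
        tree = make_study_fixture(config.seed)
        tree_path = os.path.join(out, "tree.nwk")
        with open(tree_path, "w") as fh:
            fh.write(write_newick(tree) + "\n")
        outputs.append(tree_path)

        sim_tree = mark_foreground(tree, config.selection_foreground)
        params_bg = SiteClassParams(**config.params)
        params_fg = SiteClassParams(**{**config.params, "omega2": config.omega2})
        rep_pair = study.representative_pair(config.inject_pair)

        alignments, truths = [], {}
        for g in range(config.n_genes):
            gene_id = f"gene{g:04d}"
            selected = g < config.n_selected_genes
            params = params_fg if selected else params_bg
            seed = gene_rng_seed(config.seed, g)[0] + g
            aln, history = simulate_codon_alignment(
                sim_tree if selected else tree, params, config.n_sites, seed, gene_id=gene_id
            )
            if selected and config.n_parallel_injected:
                prot = translate(aln)
                # prefer positively selected (class 2a/2b) sites so injected
                # parallelism lands where the selection scan should also fire
                class2 = [s + 1 for s in range(config.n_sites) if history.site_class[s] >= 2]
                prot, _hist_aa, truth = inject_convergence(
                    prot, protein_view(history), tree, rep_pair,
                    n_parallel=config.n_parallel_injected, n_convergent=0, seed=seed,
                    preferred_sites=class2,
                )
                truths[gene_id] = truth
                # write the protein edit back into codons via a codon choice
                aln = _codonize(prot, aln)
            alignments.append(aln)
            log.info("simulated %s (%s)", gene_id, "selected" if selected else "background")

        fasta_dir = os.path.join(out, "alignments")
        os.makedirs(fasta_dir, exist_ok=True)
        for aln in alignments:
            write_fasta(aln, os.path.join(fasta_dir, f"{aln.gene_id}.fasta"))
        truth_path = os.path.join(out, "truth.tsv")
        _write_tsv(
            [{"gene": g, "site": s, "type": t} for g, tr in sorted(truths.items()) for s, t in tr],
            truth_path, columns=["gene", "site", "type"],
        )
        outputs.append(truth_path)
        manifest["stages"]["simulate"] = {"genes": len(alignments)}

        # -- stage 2: filter ---------------------------------------------------
        policy = FilterPolicy(min_cds_nt=config.min_cds_nt)
        filtered = [filter_alignment(a, policy) for a in alignments]
        report_path = os.path.join(out, "filter_report.tsv")
        _write_tsv(filter_report_rows(filtered), report_path)
        outputs.append(report_path)
        kept = [f for f in filtered if not f.discarded]
        manifest["stages"]["filter"] = {
            "genes_in": len(filtered),
            "genes_discarded": sum(f.discarded for f in filtered),
            "genes_analyzed": len(kept),
        }

        # -- stage 3: translate + reconstruct ---------------------------------
        recons = {}
        asr_rows = []
        for f in kept:
            prot = translate(f.alignment)
            model = default_model(prot)
            asr_tree = tree
            if config.fit_asr_lengths:
                asr_tree = fit_branch_lengths(prot, tree, model).tree
            recon = reconstruct_marginal(prot, asr_tree, model)
            recons[f.alignment.gene_id] = (recon, f)
            asr_rows.extend(reconstruction_rows(recon))
        asr_path = os.path.join(out, "ancestral_states.tsv")
        _write_tsv(asr_rows, asr_path,
                   columns=["gene", "node", "site", "state", "posterior", "tie"])
        outputs.append(asr_path)
        manifest["stages"]["asr"] = {"genes": len(recons)}

        # -- stage 4: convergence ----------------------------------------------
        echo_calls = {}
        control_calls = {}
        all_call_rows = []
        for pair in study.ECHOLOCATOR_PAIRS:
            echo_calls[pair] = _pair_calls(recons, study.representative_pair(pair))
        control_pairs = sorted({ctrl for _, ctrl in study.CONTROL_DESIGN})
        for pair in control_pairs:
            control_calls[pair] = _pair_calls(recons, study.representative_pair(pair))
        for calls_by_gene in list(echo_calls.values()) + list(control_calls.values()):
            for gene_calls in calls_by_gene.values():
                all_call_rows.extend(_original_coord_rows(gene_calls, recons))
        calls_path = os.path.join(out, "convergence_calls.tsv")
        _write_tsv(all_call_rows, calls_path,
                   columns=["gene", "site", "pair", "type", "derived", "parent_a", "parent_b"])
        outputs.append(calls_path)

        summaries, core = summarize_pairs(echo_calls, list(study.ECHOLOCATOR_PAIRS))
        summary_path = os.path.join(out, "pair_summary.tsv")
        _write_tsv([
            {"pair": study.pair_label(s.pair), "parallel_genes": s.parallel_genes,
             "parallel_sites": s.parallel_sites, "convergent_genes": s.convergent_genes,
             "convergent_sites": s.convergent_sites}
            for s in summaries
        ], summary_path)
        outputs.append(summary_path)
        manifest["stages"]["converge"] = {
            "pairs": len(summaries), "core_parallel_genes": sorted(core),
        }

        # -- stage 5: selection scan -------------------------------------------
        sel_results = []
        for cfg_name in config.foreground_configs:
            tagged = mark_foreground(tree, cfg_name)
            sel_results.extend(scan_genes(
                [f.alignment for f in kept], tagged, cfg_name,
                n_starts=config.n_starts, beb_threshold=config.beb_threshold,
            ))
        sel_path = os.path.join(out, "selection_results.tsv")
        _write_tsv(results_rows(sel_results), sel_path)
        outputs.append(sel_path)
        significant = [r for r in sel_results if r.q_value < config.fdr_threshold]
        manifest["stages"]["select"] = {
            "tests": len(sel_results), "fdr_significant": len(significant),
        }

        # -- stage 6: control stats --------------------------------------------
        table = _paired_table(echo_calls, control_calls)
        table_path = os.path.join(out, "paired_counts.tsv")
        _write_tsv(table_rows(table), table_path)
        outputs.append(table_path)
        try:
            report = t_test_report(table)
        except ValueError as exc:
            report = [{"metric": m, "t": float("nan"), "df": len(table.rows) - 1,
                       "P": float("nan"), "P_2dp": float("nan"), "note": str(exc)}
                      for m in METRICS]
        report_path2 = os.path.join(out, "paired_t_tests.tsv")
        _write_tsv(report, report_path2)
        outputs.append(report_path2)

        selected_sites = {
            r.gene_id: {} for r in sel_results
        }
        for r in sel_results:
            sites = [
                _to_original(recons, r.gene_id, s)
                for s, post in r.beb if post > r.beb_threshold
            ]
            if sites:
                selected_sites[r.gene_id][r.config] = sites
        parallel_sites = {}
        for pair, by_gene in echo_calls.items():
            for gene, cs in by_gene.items():
                sites = [_to_original(recons, gene, c.site) for c in cs if c.type == "parallel"]
                if sites:
                    parallel_sites.setdefault(gene, {})[study.pair_label(pair)] = sites
        overlap = adaptive_overlap(
            {g: v for g, v in selected_sites.items() if v}, parallel_sites
        )
        overlap_path = os.path.join(out, "adaptive_overlap.tsv")
        _write_tsv([
            {"gene": o.gene_id, "site": o.site,
             "configurations": ",".join(o.configurations), "pairs": ",".join(o.pairs)}
            for o in overlap
        ], overlap_path, columns=["gene", "site", "configurations", "pairs"])
        outputs.append(overlap_path)
        manifest["stages"]["control_stats"] = {"overlap_records": len(overlap)}
        manifest["complete"] = True
    except Exception as exc:  # record partial completion, then re-raise
        manifest["complete"] = False
        manifest["error"] = str(exc)
        _finalize(manifest, outputs, out)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()

    _finalize(manifest, outputs, out)
    return manifest


def _finalize(manifest: dict, outputs: list[str], out: str) -> None:
    for path in outputs:
        if os.path.exists(path):
            manifest["checksums"][os.path.basename(path)] = _sha256(path)
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _codonize(prot, codon_aln):
    """Rewrite codon rows so they translate to the edited protein rows,
    substituting a codon of the new residue where the protein was edited."""
    from echoconv.codons import CODON_AA, CODON_INDEX, SENSE_CODONS, codons_of
    aa_to_codon = {}
    for codon, aa in zip(SENSE_CODONS, CODON_AA):
        aa_to_codon.setdefault(aa, codon)
    new_rows = []
    for taxon, pseq in zip(prot.taxa, prot.sequences):
        codons = codons_of(codon_aln.row(taxon))
        for i, aa in enumerate(pseq):
            cur = codons[i]
            cur_aa = CODON_AA[CODON_INDEX[cur]] if cur in CODON_INDEX else None
            if cur_aa != aa:
                codons[i] = aa_to_codon[aa]
        new_rows.append("".join(codons))
    from echoconv.align import CodonAlignment
    return CodonAlignment(gene_id=codon_aln.gene_id, taxa=prot.taxa, sequences=tuple(new_rows))


def _pair_calls(recons: dict, taxon_pair: tuple[str, str]) -> dict:
    out = {}
    for gene, (recon, _f) in recons.items():
        calls = classify_pair(recon, taxon_pair[0], taxon_pair[1])
        if calls:
            out[gene] = calls
    return out


def _to_original(recons: dict, gene: str, filtered_site: int) -> int:
    _recon, f = recons[gene]
    return f.original_site(filtered_site)


def _original_coord_rows(gene_calls, recons) -> list[dict]:
    rows = calls_rows(gene_calls)
    for row in rows:
        row["site"] = _to_original(recons, row["gene"], row["site"])
    return rows


def _paired_table(echo_calls: dict, control_calls: dict) -> PairedCountTable:
    """Assemble the 7-row paired table from per-pair call sets."""
    def metrics(by_gene: dict) -> dict:
        return {
            "parallel_genes": sum(
                1 for cs in by_gene.values() if any(c.type == "parallel" for c in cs)),
            "parallel_sites": sum(
                1 for cs in by_gene.values() for c in cs if c.type == "parallel"),
            "convergent_genes": sum(
                1 for cs in by_gene.values() if any(c.type == "convergent" for c in cs)),
            "convergent_sites": sum(
                1 for cs in by_gene.values() for c in cs if c.type == "convergent"),
        }

    rows = []
    for echo_pair, ctrl_pair in study.CONTROL_DESIGN:
        rows.append(PairedRow(
            echo_label=study.pair_label(echo_pair),
            control_label=study.pair_label(ctrl_pair),
            echo=metrics(echo_calls[echo_pair]),
            control=metrics(control_calls[ctrl_pair]),
        ))
    return PairedCountTable(rows=tuple(rows))
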