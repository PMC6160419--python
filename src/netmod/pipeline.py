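"""End-to-end orchestration: rank -> boundary -> neighborhood -> LCC
significance -> candidate closeness -> module assembly -> expression
validation, with one global seed fanned out to every stochastic stage and a
machine-readable run report."""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import cab as cab_mod
from .assembly import assemble_module
from .cab import CabParams, score_candidates
from .interactome import GeneSet, read_edge_list, read_gene_set, write_gene_set
from .neighborhood import (
    build_neighborhood,
    degree_adjusted_ranks,
    lcc_significance,
    plateau_cutoff,
)
from .validation import enrichment_test, foldchange_comparison, overlap_test, read_de_table

logger = logging.getLogger("netmod")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    network: str
    seeds: str
    outdir: str
    gwas: str | None = None
    candidates: str | None = None
    de_tables: list[str] = field(default_factory=list)
    signature: str | None = None
    restart: float = 0.75
    weighted: bool = True
    window: int = 25
    alpha: float = 0.05
    force_k: int | None = None
    p_exponents: list[float] = field(default_factory=lambda: [0.0, 1.0, 2.0, 10.0])
    reporting_p_exponent: float = 1.0
    n_rand_cab: int = 10_000
    n_rand_lcc: int = 10_000
    z_threshold: float = -1.6
    steiner_hops: bool = False
    de_p_thresh: float = 0.05
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def validate_paths(self) -> None:
        for p in [self.network, self.seeds, self.gwas, self.candidates, self.signature, *self.de_tables]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _stage_seed(base: int, stage: int) -> int:
    return (int(base) * 1_000_003 + stage) % (2**31 - 1)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow; artifacts go to ``cfg.outdir`` and the
    returned report is also written there as ``report.json``."""
    cfg.validate_paths()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(cfg), "stages": {}}

    stage = "rank"
    try:
        G = read_edge_list(cfg.network)
        seeds = read_gene_set(cfg.seeds, "seeds")
        ranked = degree_adjusted_ranks(G, seeds, restart=cfg.restart, weighted=cfg.weighted)
        with open(outdir / "ranked.tsv", "w") as fh:
            fh.write("gene\traw\tadjusted\trank\n")
            for g, raw, adj, rank in ranked.to_rows():
                fh.write(f"{g}\t{raw:.10g}\t{adj:.10g}\t{rank}\n")
        report["stages"]["rank"] = {"n_nodes": G.number_of_nodes(), "n_ranked": len(ranked)}

        stage = "boundary"
        if cfg.force_k is not None:
            cutoff = int(cfg.force_k)
        elif cfg.gwas:
            pvals = {}
            with open(cfg.gwas) as fh:
                header = fh.readline()
                for line in fh:
                    g, p = line.split()[:2]
                    pvals[g.strip().upper()] = float(p)
            cutoff = plateau_cutoff(ranked, pvals, window=cfg.window, alpha=cfg.alpha)
        else:
            raise ValueError("boundary stage needs either gwas p-values or force_k")
        report["stages"]["boundary"] = {"cutoff_k": cutoff}

        stage = "neighborhood"
        nbhd = build_neighborhood(G, ranked, seeds, cutoff)
        write_gene_set(nbhd.neighborhood.members, outdir / "neighborhood.txt")
        report["stages"]["neighborhood"] = {
            "n_components": len(nbhd.components),
            "component_sizes": sorted((len(c) for c in nbhd.components), reverse=True),
            "neighborhood_size": nbhd.neighborhood.size,
            "n_seedless": len(nbhd.seedless),
        }

        stage = "lcc_significance"
        lcc = lcc_significance(
            G, nbhd.neighborhood, n_rand=cfg.n_rand_lcc, seed=_stage_seed(cfg.rng_seed, 4)
        )
        report["stages"]["lcc_significance"] = {
            "lcc_size": lcc.lcc_size, "z": lcc.z, "empirical_p": lcc.empirical_p,
        }

        stage = "cab"
        significant = GeneSet(name="significant", members=frozenset())
        if cfg.candidates:
            params = CabParams(
                p_grid=tuple(math.exp(e) for e in cfg.p_exponents),
                reporting_p=math.exp(cfg.reporting_p_exponent),
                n_rand=cfg.n_rand_cab,
                z_threshold=cfg.z_threshold,
                rng_seed=_stage_seed(cfg.rng_seed, 5),
            )
            candidates = read_gene_set(cfg.candidates, "candidates")
            results, significant, unmapped = score_candidates(G, candidates, nbhd.neighborhood, params)
            with open(outdir / "cab.tsv", "w") as fh:
                fh.write("candidate\tp\tobserved\tnull_mean\tnull_sd\tz\tempirical_p\tsignificant\n")
                for r in results:
                    fh.write(
                        f"{r.candidate}\t{r.p:.6g}\t{r.observed:.6g}\t{r.null_mean:.6g}\t"
                        f"{r.null_sd:.6g}\t{r.z:.4f}\t{r.empirical_p:.6g}\t{int(r.significant)}\n"
                    )
            write_gene_set(significant.members, outdir / "cab_significant.txt")
            report["stages"]["cab"] = {
                "n_candidates": candidates.size,
                "n_significant": significant.size,
                "n_unmapped": unmapped.size,
            }

        stage = "assemble"
        steiner_p = 1.0 if cfg.steiner_hops else math.exp(cfg.reporting_p_exponent)
        module = assemble_module(nbhd, significant, G, p=steiner_p)
        write_gene_set(module.members.members, outdir / "module.txt")
        with open(outdir / "module_provenance.tsv", "w") as fh:
            fh.write("gene\trole\n")
            for g, role in sorted(module.provenance.items()):
                fh.write(f"{g}\t{role}\n")
        overlap_count = len(nbhd.neighborhood.members & significant.members)
        report["stages"]["assemble"] = {
            "n_terminals": module.terminals.size,
            "n_linkers": module.linkers.size,
            "module_size": module.total_size,
            "terminal_overlap": overlap_count,
            "linkers": sorted(module.linkers.members),
        }

        stage = "validate"
        if cfg.de_tables:
            validations = []
            for path in cfg.de_tables:
                table = read_de_table(path)
                entry: dict = {"dataset": table.dataset}
                try:
                    vr = foldchange_comparison(module.members, table, p_thresh=cfg.de_p_thresh)
                    entry["foldchange"] = asdict(vr)
                except ValueError as exc:
                    entry["foldchange_error"] = str(exc)
                de = table.de_genes(p_thresh=cfg.de_p_thresh)
                enr = enrichment_test(module.members, de, universe=table.genes.size)
                entry["enrichment"] = asdict(enr)
                validations.append(entry)
            report["stages"]["validate"] = validations

        if cfg.signature:
            signature = read_gene_set(cfg.signature, "signature")
            ov = overlap_test(module.members, signature, universe=G.number_of_nodes())
            report["stages"]["signature_overlap"] = asdict(ov)
    except Exception as exc:
        report["failed_stage"] = stage
        report["error"] = str(exc)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
        raise

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
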