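"""End-to-end workflow orchestration.

``run_pipeline`` executes the full analysis (data -> diversity ->
differentiation -> clustering -> haplotype network -> ABC) on either the
synthetic study fixture or user-supplied files, writing per-stage TSV
artifacts plus a consolidated summary.  A single global seed determines
every stochastic output; each artifact's header comment records the package
version and seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import hydropop
from hydropop import io as hio
from hydropop import (
    GroupingScheme,
    read_fasta_alignment,
    read_genepop,
    read_metadata,
)
from hydropop.fixture import (
    ABC_GROUPS,
    MISMATCHED,
    REDUCED_LOCUS_SET,
    czoder_families,
    make_study_fixture,
    sazava_families,
    study_loci,
)

log = logging.getLogger("hydropop")


@dataclass
class RunConfig:
    """Pipeline configuration.

    Either ``fixture_seed`` (generate the synthetic study dataset) or
    ``genepop_path`` (+ optional metadata/FASTA) must be given.
    """

    out_dir: str = "hydropop_out"
    seed: int = 1
    fixture_seed: int | None = None
    genepop_path: str | None = None
    metadata_path: str | None = None
    fasta_path: str | None = None
    stages: tuple = ("diversity", "diff", "structure", "network", "abc")
    # stage parameters (desk scale)
    n_perm_fst: int = 200
    n_perm_amova: int = 2000
    n_perm_rst: int = 2000
    k_range: tuple = (1, 4)
    k_replicates: int = 2
    gibbs_iters: int = 2000
    gibbs_burnin: int = 500
    abc_sims_per_scenario: int = 500
    abc_tolerance: float = 0.05
    mismatched_populations: tuple = tuple(MISMATCHED)
    amova_groups: dict | None = None  # population -> group; default watershed subset

    def validate(self):
        if self.fixture_seed is None and self.genepop_path is None:
            raise hio.ValidationError("need fixture_seed or genepop_path")


def _write_tsv(df: pd.DataFrame, path: Path, seed: int, index=False):
    with open(path, "w") as fh:
        fh.write(f"# hydropop {hydropop.__version__} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=index)


def _amova_subset_groups(grouping: GroupingScheme):
    """Watershed AMOVA on the populations adjacent to the divides:
    Elbe basin vs Danube (Morava) basin vs Oder basin."""
    sel = {}
    for p in grouping.populations:
        if p.startswith("ELB"):
            sel[p] = "elbe"
        elif p in ("DAN1", "DAN2", "DAN4", "DAN5", "DAN6", "DAN7",
                   "DAN8", "DAN9", "DAN10"):
            sel[p] = "danube"
        elif p.startswith("ODR"):
            sel[p] = "oder"
    return sel


def run_pipeline(config: RunConfig) -> dict:
    """Run all enabled stages; returns a dict of result objects.

    Fails fast with the stage name on error; artifacts of completed stages
    are retained.
    """
    config.validate()
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    results: dict = {"config": config}

    # -- data ---------------------------------------------------------------
    stage = "data"
    try:
        if config.fixture_seed is not None:
            table, grouping, aln = make_study_fixture(config.fixture_seed)
        else:
            table = read_genepop(config.genepop_path, loci=None)
            grouping = read_metadata(config.metadata_path) if config.metadata_path else None
            aln = read_fasta_alignment(config.fasta_path) if config.fasta_path else None
        hio.write_genepop(table, out / "genotypes.gen")
        results["table"], results["grouping"], results["alignment"] = table, grouping, aln
        log.info("data: %d individuals, %d loci, %d populations",
                 table.n_individuals, table.n_loci, len(table.population_labels()))

        if "diversity" in config.stages:
            stage = "diversity"
            from hydropop.diversity import diversity_table

            div = diversity_table(table)
            _write_tsv(div, out / "diversity.tsv", config.seed)
            means = div.groupby("population", sort=False)[["Ho", "He", "AR_18"]].mean()
            reduced = [l for l in REDUCED_LOCUS_SET if l in table.locus_names]
            if reduced:
                means_reduced = (
                    div[div["locus"].isin(reduced)]
                    .groupby("population", sort=False)[["Ho", "He", "AR_18"]]
                    .mean()
                )
                means = means.join(means_reduced, rsuffix="_reduced")
            _write_tsv(means, out / "diversity_population_means.tsv", config.seed, index=True)
            results["diversity"] = div
            log.info("diversity: wrote %d rows", len(div))

        if "diff" in config.stages:
            stage = "diff"
            from hydropop.differentiation import (
                Amova,
                allele_size_permutation_test,
                fst_matrix,
                ibd_regression,
                rst,
            )

            if config.n_perm_fst:
                fst, fst_p = fst_matrix(
                    table, n_perm=config.n_perm_fst, seed=int(rng.integers(1, 2**31 - 1))
                )
            else:
                fst = fst_matrix(table)
                fst_p = pd.DataFrame(np.nan, index=fst.index, columns=fst.columns)
            # Table-2-style layout: F_ST above the diagonal, R_ST below
            pops = list(fst.index)
            rst_m = pd.DataFrame(np.nan, index=pops, columns=pops)
            for i in range(len(pops)):
                for j in range(i + 1, len(pops)):
                    rst_m.iloc[j, i] = rst(table, [pops[i], pops[j]])
            combined = fst.where(np.triu(np.ones(fst.shape, dtype=bool), 1))
            combined = combined.fillna(rst_m)
            _write_tsv(combined, out / "fst_rst_matrix.tsv", config.seed, index=True)
            _write_tsv(fst_p, out / "fst_pvalues.tsv", config.seed, index=True)
            results["fst"], results["fst_p"] = fst, fst_p
            global_rst = allele_size_permutation_test(
                table, n_perm=config.n_perm_rst, seed=int(rng.integers(1, 2**31 - 1))
            )
            results["rst_global"] = global_rst
            amova_groups = config.amova_groups or (
                _amova_subset_groups(grouping) if grouping else None
            )
            if amova_groups:
                res_all = Amova(table, amova_groups).fit(
                    n_perm=config.n_perm_amova, seed=int(rng.integers(1, 2**31 - 1))
                )
                keep = {p: g for p, g in amova_groups.items()
                        if p not in config.mismatched_populations}
                res_reduced = Amova(table, keep).fit(
                    n_perm=config.n_perm_amova, seed=int(rng.integers(1, 2**31 - 1))
                )
                amova_df = pd.DataFrame(
                    [
                        {"analysis": "all_populations", "F_CT": res_all.f_ct,
                         "F_SC": res_all.f_sc, "F_ST": res_all.f_st, "p_FCT": res_all.p_fct},
                        {"analysis": "mismatched_removed", "F_CT": res_reduced.f_ct,
                         "F_SC": res_reduced.f_sc, "F_ST": res_reduced.f_st,
                         "p_FCT": res_reduced.p_fct},
                    ]
                )
                _write_tsv(amova_df, out / "amova.tsv", config.seed)
                results["amova_all"], results["amova_reduced"] = res_all, res_reduced
                log.info("AMOVA F_CT: %.4f -> %.4f after removing %s",
                         res_all.f_ct, res_reduced.f_ct, list(config.mismatched_populations))
            if grouping is not None:
                dan = [p for p in pops if p.startswith("DAN")][:10]
                if len(dan) >= 4:
                    ibd = ibd_regression(
                        fst, grouping, dan, seed=int(rng.integers(1, 2**31 - 1))
                    )
                    _write_tsv(ibd.summary().to_frame().T, out / "ibd.tsv", config.seed)
                    results["ibd"] = ibd

        if "structure" in config.stages:
            stage = "structure"
            from hydropop.clustering import AdmixtureModel, align_runs, fca, scan_k

            ks = list(range(config.k_range[0], config.k_range[1] + 1))
            series = scan_k(
                table, ks, replicates=config.k_replicates,
                iters=config.gibbs_iters, burnin=config.gibbs_burnin,
                seed=int(rng.integers(1, 2**31 - 1)),
            )
            _write_tsv(series.to_frame(), out / "delta_k.tsv", config.seed)
            results["delta_k"] = series
            runs = [
                AdmixtureModel(table, 2).fit(
                    iters=config.gibbs_iters, burnin=config.gibbs_burnin,
                    seed=int(rng.integers(1, 2**31 - 1)),
                )
                for _ in range(config.k_replicates)
            ]
            mean_q, _, _ = align_runs([r.Q for r in runs])
            qdf = pd.DataFrame(mean_q, index=runs[0].model.individuals,
                               columns=["cluster_1", "cluster_2"])
            qdf.insert(0, "population", runs[0].model.populations)
            _write_tsv(qdf, out / "q_matrix_k2.tsv", config.seed, index=True)
            results["q_k2"] = qdf
            try:
                results["fca"] = fca(table)
                _write_tsv(results["fca"].centroids, out / "fca_centroids.tsv",
                           config.seed, index=True)
            except hio.ValidationError:
                pass
            try:
                import matplotlib

                matplotlib.use("Agg")
                ax = runs[0].barplot()
                ax.figure.savefig(out / "structure_k2.png", dpi=120)
            except Exception:  # plotting is best-effort
                log.info("structure: barplot skipped")

        if "network" in config.stages and aln is not None:
            stage = "network"
            from hydropop.haplonet import collapse_haplotypes, median_joining, write_network

            haps = collapse_haplotypes(aln)
            net = median_joining(haps)
            _write_tsv(haps.table(), out / "haplotypes.tsv", config.seed, index=True)
            write_network(net, tsv_path=out / "network_edges.tsv",
                          gml_path=out / "network.gml")
            results["haplotypes"], results["network"] = haps, net
            log.info("network: %d haplotypes, %d nodes", haps.n_haplotypes,
                     net.number_of_nodes())

        if "abc" in config.stages and grouping is not None:
            stage = "abc"
            from hydropop.abc import build_reference, model_choice, summary_statistics

            abc_rows = []
            for label, fams, members in (
                ("SAZAVA", sazava_families(), ("SAZAVA", "CZELBE", "WMORAV")),
                ("CZODER", czoder_families(), ("CZODER", "NMORAV", "POLRIV")),
            ):
                groups = {g: ABC_GROUPS[g] for g in members}
                if not all(any(p in table.population_labels() for p in v)
                           for v in groups.values()):
                    continue
                obs = summary_statistics(table, groups)
                sizes = {
                    g: int(sum(table.pop_mask(v).sum() for v in [groups[g]]))
                    for g in groups
                }
                ref = build_reference(
                    fams, config.abc_sims_per_scenario, sizes,
                    n_loci=table.n_loci, allele_range=50,
                    seed=int(rng.integers(1, 2**31 - 1)),
                )
                mc = model_choice(ref, obs, tolerance=config.abc_tolerance)
                mc.posterior.insert(0, "analysis", label)
                abc_rows.append(mc.posterior)
                results[f"abc_{label.lower()}"] = mc
                log.info("ABC %s: best scenario %s", label, mc.best())
            if abc_rows:
                _write_tsv(pd.concat(abc_rows), out / "abc_model_choice.tsv", config.seed)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "version": hydropop.__version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "runtime_s": round(time.time() - t_start, 2),
        "artifacts": sorted({p.name for p in out.iterdir()} | {"run.json"}),
    }
    with open(out / "run.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    results["manifest"] = manifest
    return results
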