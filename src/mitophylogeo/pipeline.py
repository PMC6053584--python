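"""Config-driven orchestration of the full mitogenome phylogeography analysis.

One logical seed fans out to per-stage seeds through a recorded spawn
counter, so any stage can be rerun in isolation with the seed noted in the
run log.  All reports are TSV/JSON; reruns with the same seed are
bit-identical.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .alignment import classify_sites, collapse_haplotypes, read_alignment
from .distance import difference_matrix
from .diversity import (
    divergence_rate,
    diversity_summary,
    expansion_time,
    fit_sudden_expansion,
    mismatch_distribution,
)
from .montecarlo import PartitionModel, mc_phylogeo_test, mc_table
from .network import build_network, connection_limit, to_dot, to_edge_tsv, to_graphml
from .phylogeny import (
    bootstrap_support,
    clock_node_ages,
    root_with_outgroup,
    tree_to_newick,
)
from .popmap import read_coordinates, read_population_map
from .samova import samova_search
from .simulate import SimulationConfig, generate_dataset
from .structure import (
    amova,
    geographic_distance_matrix,
    mantel_ibd,
    pairwise_phist,
    pcoa,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    output_dir: str = "results"
    seed: int = 1
    # inputs: either paths or a synthetic config
    alignment: str | None = None
    population_map: str | None = None
    coordinates: str | None = None
    montecarlo_models: str | None = None  # TSV, optional
    synthetic: dict | None = None
    # stage toggles
    stages: tuple[str, ...] = (
        "sites", "diversity", "structure", "samova", "phylogeny",
        "network", "mismatch", "montecarlo",
    )
    # analysis parameters
    amova_permutations: int = 100_000
    mantel_permutations: int = 10_000
    bootstrap_replicates: int = 10_000
    mc_randomizations: int = 10_000
    samova_k: tuple[int, ...] = (2, 3, 4)
    samova_runs: int = 100
    samova_steps: int = 10_000
    samova_permutations: int = 1_000
    alpha: float = 0.05
    min_pop_n: int = 3
    calibration_age_years: float = 3.8e6
    mean_root_distance: float = 0.039
    genome_length: int | None = None
    network_confidence: float = 0.90
    outgroup: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        if isinstance(cfg.samova_k, list):
            cfg.samova_k = tuple(cfg.samova_k)
        return cfg


@dataclass
class _SeedFanout:
    """Derives a per-stage 31-bit seed; the counter is recorded in the log."""

    root: int
    log: dict[str, int] = field(default_factory=dict)
    _counter: int = 0

    def seed_for(self, stage: str) -> int:
        seed = int(
            np.random.SeedSequence([self.root, self._counter]).generate_state(1)[0]
            % (2**31)
        )
        self.log[stage] = self._counter
        self._counter += 1
        return seed


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages; emit the report bundle; return the artifacts."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    fan = _SeedFanout(config.seed)
    run_log: dict = {
        "version": __version__,
        "seed": config.seed,
        "python": sys.version.split()[0],
        "stages": list(config.stages),
        "parameters": {
            "amova_permutations": config.amova_permutations,
            "mantel_permutations": config.mantel_permutations,
            "bootstrap_replicates": config.bootstrap_replicates,
            "mc_randomizations": config.mc_randomizations,
            "alpha": config.alpha,
            "calibration_age_years": config.calibration_age_years,
        },
    }
    artifacts: dict = {}
    try:
        # ------------------------------------------------------------- inputs
        if config.synthetic is not None:
            sim = SimulationConfig(**{**config.synthetic, "seed": config.seed})
            data = generate_dataset(sim, outdir / "synthetic")
            aln = data["alignment"]
            assignment = data["assignment"]
            coords = data["coordinates"]
            run_log["input"] = "synthetic"
        else:
            if not config.alignment or not config.population_map:
                raise PipelineError("alignment and population_map are required")
            for key in ("alignment", "population_map", "coordinates",
                        "montecarlo_models"):
                p = getattr(config, key)
                if p is not None and not Path(p).exists():
                    raise PipelineError(f"{key} file not found: {p}")
            aln = read_alignment(config.alignment)
            assignment = read_population_map(config.population_map)
            coords = (
                read_coordinates(config.coordinates)
                if config.coordinates
                else None
            )
            run_log["input"] = str(config.alignment)
        genome_length = config.genome_length or aln.length
        dist = difference_matrix(aln)
        haplotypes = collapse_haplotypes(aln, assignment.sample_to_population)
        artifacts.update(
            alignment=aln, assignment=assignment, distance=dist,
            haplotypes=haplotypes,
        )

        if "sites" in config.stages:
            sites = classify_sites(aln)
            (outdir / "site_classification.json").write_text(
                json.dumps(sites.to_dict(), indent=1)
            )
            artifacts["sites"] = sites

        if "diversity" in config.stages:
            import pandas as pd

            rows = diversity_summary(aln, haplotypes, assignment)
            df = pd.DataFrame(rows)
            total = {
                "population": "Total",
                "n": aln.n,
                "h": haplotypes.n_haplotypes,
            }
            df = pd.concat([df, pd.DataFrame([total])], ignore_index=True)
            df.to_csv(outdir / "diversity_table.tsv", sep="\t", index=False,
                      float_format="%.4f")
            artifacts["diversity"] = df

        if "structure" in config.stages:
            seed = fan.seed_for("amova")
            res = amova(dist, assignment, n_perm=config.amova_permutations,
                        seed=seed)
            (outdir / "amova.json").write_text(json.dumps({
                "phi_st": res.phi_st,
                "percent_variation": res.percent_variation,
                "p_values": res.p_values,
                "n_permutations": res.n_permutations,
                "seed": seed,
            }, indent=1))
            artifacts["amova"] = res
            seed = fan.seed_for("pairwise_phist")
            pw = pairwise_phist(
                dist, assignment, n_perm=config.amova_permutations,
                seed=seed, min_pop_n=config.min_pop_n, alpha=config.alpha,
            )
            pw.phi.to_csv(outdir / "phist_matrix.tsv", sep="\t",
                          float_format="%.4f")
            pw.p.to_csv(outdir / "phist_pvalues.tsv", sep="\t",
                        float_format="%.5f")
            pw.render().to_csv(outdir / "phist_table.tsv", sep="\t")
            (outdir / "phist_meta.json").write_text(json.dumps({
                "p_crit": pw.p_crit, "m": pw.m, "excluded": pw.excluded,
                "n_permutations": pw.n_permutations, "seed": seed,
            }, indent=1))
            artifacts["pairwise_phist"] = pw
            if coords is not None:
                geo = geographic_distance_matrix(coords).submatrix(pw.populations)
                from .distance import DistanceMatrix

                gen = DistanceMatrix(pw.populations, pw.phi.to_numpy())
                seed = fan.seed_for("mantel")
                try:
                    mres = mantel_ibd(gen, geo,
                                      n_perm=config.mantel_permutations,
                                      seed=seed)
                    (outdir / "mantel.json").write_text(json.dumps({
                        "r": mres.r, "p": mres.p, "R2": mres.r_squared,
                        "n_permutations": mres.n_permutations, "seed": seed,
                    }, indent=1))
                    artifacts["mantel"] = mres
                except ValueError as err:
                    logger.warning("Mantel test skipped: %s", err)
            pc = pcoa(dist, n_axes=3)
            pc.coordinates.to_csv(outdir / "pcoa_individuals.tsv", sep="\t",
                                  float_format="%.5f")
            artifacts["pcoa"] = pc

        if "samova" in config.stages and coords is not None:
            import pandas as pd

            rows = []
            for k in config.samova_k:
                seed = fan.seed_for(f"samova_k{k}")
                sres = samova_search(
                    dist, assignment, coords, K=k,
                    n_runs=config.samova_runs, n_steps=config.samova_steps,
                    seed=seed, n_perm=config.samova_permutations,
                )
                rows.append({
                    "K": k, "phi_ct": sres.phi_ct, "p": sres.p_value,
                    "grouping": json.dumps(sres.grouping), "seed": seed,
                })
            pd.DataFrame(rows).to_csv(outdir / "samova.tsv", sep="\t",
                                      index=False, float_format="%.4f")
            artifacts["samova"] = rows

        if "phylogeny" in config.stages:
            seed = fan.seed_for("bootstrap")
            tree = bootstrap_support(
                aln, n_reps=config.bootstrap_replicates, seed=seed
            )
            (outdir / "tree.nwk").write_text(tree_to_newick(tree) + "\n")
            artifacts["tree"] = tree
            if config.outgroup:
                per_site = difference_matrix(aln, per_site=True)
                from .phylogeny import nj_tree

                rooted = root_with_outgroup(nj_tree(per_site), config.outgroup)
                dated, ages, ingroup_age = clock_node_ages(
                    rooted, config.calibration_age_years, config.outgroup
                )
                ages.to_csv(outdir / "node_ages.tsv", sep="\t", index=False,
                            float_format="%.1f")
                artifacts["node_ages"] = ages
                artifacts["ingroup_age"] = ingroup_age

        if "network" in config.stages:
            limit = connection_limit(genome_length, config.network_confidence)
            net = build_network(haplotypes, limit)
            to_graphml(net, outdir / "network.graphml")
            to_edge_tsv(net, outdir / "network_edges.tsv")
            (outdir / "network.dot").write_text(to_dot(net))
            (outdir / "network_meta.json").write_text(json.dumps({
                "max_steps": limit.max_steps,
                "confidence": limit.confidence,
                "n_components": len(net.components),
                "n_latent": len(net.latent),
            }, indent=1))
            artifacts["network"] = net

        if "mismatch" in config.stages:
            mm = fit_sudden_expansion(mismatch_distribution(aln))
            clock = divergence_rate(
                config.mean_root_distance, config.calibration_age_years,
                genome_length,
            )
            est = expansion_time(mm.tau_hat, clock)
            (outdir / "expansion.json").write_text(json.dumps({
                "tau_hat": mm.tau_hat, "theta0": mm.theta0,
                "theta1": mm.theta1, "SSD": mm.fit_SSD,
                "mean_pairwise_differences": mm.mean_diff,
                "divergence_rate": clock.divergence_rate,
                "expansion_time_years": est.t_years,
            }, indent=1))
            import pandas as pd

            pd.DataFrame({
                "differences": np.arange(len(mm.histogram)),
                "n_pairs": mm.histogram,
            }).to_csv(outdir / "mismatch.tsv", sep="\t", index=False)
            artifacts["expansion"] = est
            artifacts["mismatch"] = mm

        if "montecarlo" in config.stages and "tree" in artifacts:
            models = []
            if config.montecarlo_models:
                models.append(PartitionModel.from_tsv(config.montecarlo_models))
            elif assignment.population_to_group is not None:
                parts: dict[int, set[str]] = {}
                names = sorted(set(assignment.population_to_group.values()))
                for i, g in enumerate(names, start=1):
                    parts[i] = {
                        p for p, gg in assignment.population_to_group.items()
                        if gg == g
                    }
                models.append(PartitionModel("groups", parts))
            else:
                # no a-priori grouping: four contiguous quarters of the
                # population list as a default geographic partition model
                pops = list(assignment.populations)
                quarters: dict[int, set[str]] = {}
                for i, chunk in enumerate(np.array_split(pops, 4), start=1):
                    if len(chunk):
                        quarters[i] = set(chunk)
                models.append(PartitionModel("quarters", quarters))
            results = []
            for model in models:
                seed = fan.seed_for(f"montecarlo_{model.model_id}")
                results.append(mc_phylogeo_test(
                    artifacts["tree"], assignment, model,
                    n_rand=config.mc_randomizations, seed=seed,
                ))
            if results:
                mc_table(results).to_csv(outdir / "montecarlo.tsv", sep="\t",
                                         index=False)
                artifacts["montecarlo"] = results
    except PipelineError:
        raise
    except Exception as err:
        (outdir / "run_log.json").write_text(json.dumps(
            {**run_log, "stage_seeds": fan.log, "error": str(err)}, indent=1
        ))
        raise PipelineError(f"stage failure: {err}") from err
    run_log["stage_seeds"] = fan.log
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=1))
    return artifacts
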