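"""End-to-end orchestration of the fold-mining workflow.

The demo pipeline mirrors the mining flowchart on synthetic data:
simulate a trefoil family → build (or parse) a search table → run both
filtering iterations → pick one representative per domain architecture
→ classify architectures against a catalog → structure-based MSA →
gap-filter columns → entropy profile → core-position extraction →
neighbor-joining trees on the full and core alignments → clade-purity
report.  Every stage writes its artifact plus one JSON log line with
input/output counts; a rerun with the same config and seed is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import conservation, mining, phylogeny, simulate, structure_io, superpose
from .architecture import find_novel_architectures
from .errors import ConfigError, PipelineStageError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the demo pipeline needs; the seed is mandatory.

    The filtering, gap and selection defaults are the working thresholds
    of the mining workflow: 2 Å / 80% coverage for the strict first
    iteration, 3 Å / 30% for the relaxed second, a 10% column gap
    ceiling, a 9-column low-entropy selection with a 7-column core, and
    4-way clade cuts for the purity report.
    """

    seed: int
    outdir: str = "trefoilkit_run"
    # generator
    n_taxa: int = 64
    n_columns: int = 150
    core_size: int = 7
    n_function_groups: int = 4
    substitution_rate: float = 1.5
    structure_noise_scale: float = 2.0
    gap_rate: float = 0.05
    core_mode: str = "invariant"
    function_from_clades: bool = True
    kingdom_from_clades: bool = False
    # search / filtering
    search_n_hits: int = 500
    external_search_table: str | None = None
    external_dialect: str = "foldseek"
    external_query_length: int | None = None
    # structure MSA
    run_structure_msa: bool = True
    reference_id: str | None = None   # default: first simulated taxon
    msa_min_coverage: float = 0.5
    dist_cutoff: float = 5.0
    # conservation
    max_gap_fraction: float = 0.10
    entropy_mode: str = "bottom_k"
    low_entropy_k: int = 9
    core_k: int = 7
    # phylogeny
    purity_k: int = 4

    def validate(self) -> None:
        if self.external_search_table is not None:
            if self.external_dialect not in ("foldseek", "dali"):
                raise ConfigError(f"unknown dialect {self.external_dialect!r}")
            if not Path(self.external_search_table).exists():
                raise ConfigError(
                    f"search table {self.external_search_table} does not exist"
                )
            if self.external_dialect == "dali" and not self.external_query_length:
                raise ConfigError("dali dialect requires external_query_length")
        if self.run_structure_msa and self.reference_id == "":
            raise ConfigError("reference_id must be a taxon id or None")
        if self.core_k > self.low_entropy_k:
            raise ConfigError("core_k cannot exceed low_entropy_k")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        data.update(overrides)
        if "seed" not in data:
            raise ConfigError("seed is mandatory in pipeline config")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def simulation_config(self, seed: int) -> simulate.SimulationConfig:
        return simulate.SimulationConfig(
            seed=seed,
            n_taxa=self.n_taxa,
            n_columns=self.n_columns,
            core_size=self.core_size,
            n_function_groups=self.n_function_groups,
            substitution_rate=self.substitution_rate,
            structure_noise_scale=self.structure_noise_scale,
            gap_rate=self.gap_rate,
            core_mode=self.core_mode,
            function_from_clades=self.function_from_clades,
            kingdom_from_clades=self.kingdom_from_clades,
        )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the run report (also written as JSON)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log.jsonl"
    report: dict = {"seed": config.seed, "stages": {}}
    log_handle = open(log_path, "w")

    def log_stage(stage: str, **counts) -> None:
        entry = {"stage": stage, **counts}
        report["stages"][stage] = counts
        log_handle.write(json.dumps(entry, sort_keys=True) + "\n")
        logger.info("stage %s: %s", stage, counts)

    def run_stage(stage: str, fn):
        try:
            return fn()
        except Exception as exc:
            log_handle.close()
            raise PipelineStageError(stage, exc) from exc

    seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2 ** 31)

    # -- simulate ----------------------------------------------------------
    def _simulate():
        template = simulate.make_template_structure(config.n_columns, int(seeds[0]))
        sim_cfg = config.simulation_config(int(seeds[1]))
        structures, msa, truth = simulate.evolve_family(template, sim_cfg)
        sdir = out / "structures"
        sdir.mkdir(exist_ok=True)
        for s in structures:
            structure_io.write_structure(s, sdir / f"{s.id}.pdb")
        structure_io.write_fasta_msa(msa, out / "simulated_alignment.fasta")
        phylogeny.write_newick(truth.true_tree, out / "true_tree.nwk")
        with open(out / "labels.tsv", "w") as h:
            h.write("taxon\tfunction\tkingdom\n")
            for t in msa.taxa:
                h.write(f"{t}\t{truth.function_labels[t]}\t{truth.kingdom_labels[t]}\n")
        conservation.write_positions(truth.core_positions, out / "planted_core.txt")
        log_stage("simulate", n_structures=len(structures), n_columns=msa.width)
        return template, structures, msa, truth

    template, structures, msa_true, truth = run_stage("simulate", _simulate)

    # -- search table ------------------------------------------------------
    def _search():
        if config.external_search_table:
            if config.external_dialect == "foldseek":
                hits = structure_io.parse_foldseek_table(config.external_search_table)
            else:
                hits = structure_io.parse_dali_table(
                    config.external_search_table, config.external_query_length
                )
            tables = {"iteration1": hits, "iteration2": hits}
        else:
            tables = {}
            for i, name in enumerate(("iteration1", "iteration2")):
                hits, t = simulate.make_search_table(
                    config.search_n_hits, name, int(seeds[2]) + i
                )
                structure_io.write_foldseek_table(hits, out / f"search_{name}.tsv")
                simulate.write_ground_truth_table(
                    hits, t, out / f"search_{name}.truth.tsv"
                )
                tables[name] = hits
        log_stage("search_table", **{k: len(v) for k, v in tables.items()})
        return tables

    tables = run_stage("search_table", _search)

    # -- filter ------------------------------------------------------------
    def _filter():
        kept = {}
        for name, hits in tables.items():
            p = mining.preset(name)
            k, rep = mining.filter_hits(hits, p)
            structure_io.write_foldseek_table(k, out / f"kept_{name}.tsv")
            log_stage(
                f"filter_{name}",
                n_input=rep.n_input,
                n_kept=rep.n_kept,
                n_rejected=rep.n_rejected,
                reasons=dict(rep.reasons),
            )
            kept[name] = k
        return kept

    kept = run_stage("filter", _filter)

    # -- representatives + classification ---------------------------------
    def _architecture():
        archs, catalog, _expected = simulate.make_architecture_fixtures(int(seeds[3]))
        # Attach a synthetic architecture to each kept hit, cycling the fixture
        # set so several hits share each signature.
        arch_map = {}
        for i, h in enumerate(kept["iteration2"]):
            proto = archs[i % len(archs)]
            arch_map[h.target_id] = dataclasses.replace(proto, protein_id=h.target_id)
        reps, rep_errors = mining.select_representatives(kept["iteration2"], arch_map)
        with open(out / "representatives.txt", "w") as h:
            h.write("\n".join(reps) + ("\n" if reps else ""))
        novel = find_novel_architectures(list(arch_map.values()), catalog)
        with open(out / "novel_architectures.tsv", "w") as h:
            h.write("protein_id\tsignature\tcategory\n")
            for pid, sig, cat in novel:
                h.write(f"{pid}\t{'+'.join(sig)}\t{cat}\n")
        log_stage(
            "architecture",
            n_representatives=len(reps),
            n_missing_annotation=len(rep_errors),
            n_novel=len(novel),
        )

    run_stage("architecture", _architecture)

    # -- structure MSA -----------------------------------------------------
    def _structure_msa():
        if not config.run_structure_msa:
            log_stage("structure_msa", skipped=True)
            return msa_true
        ref = config.reference_id or structures[0].id
        if ref not in {s.id for s in structures}:
            raise ConfigError(f"reference {ref!r} is not a simulated taxon")
        msa, rep = superpose.reference_msa(
            structures,
            ref,
            min_coverage=config.msa_min_coverage,
            dist_cutoff=config.dist_cutoff,
        )
        structure_io.write_fasta_msa(msa, out / "structure_msa.fasta")
        log_stage(
            "structure_msa",
            n_rows=msa.n_taxa,
            width=msa.width,
            n_excluded=len(rep.excluded),
        )
        return msa

    structure_msa = run_stage("structure_msa", _structure_msa)

    # -- conservation ------------------------------------------------------
    def _conservation():
        filtered, index_map = conservation.filter_columns(
            msa_true, config.max_gap_fraction
        )
        profile = conservation.entropy_profile(filtered, index_map)
        conservation.write_entropy_profile(profile, out / "entropy_profile.tsv")
        low = conservation.low_entropy_positions(
            profile, config.entropy_mode, config.low_entropy_k
        )
        core = conservation.low_entropy_positions(
            profile, config.entropy_mode, config.core_k
        )
        conservation.write_positions(low, out / "low_entropy_positions.txt")
        conservation.write_positions(core, out / "core_positions.txt")
        core_msa = conservation.extract_subalignment(msa_true, core)
        structure_io.write_fasta_msa(core_msa, out / "core_alignment.fasta")
        log_stage(
            "conservation",
            n_columns_in=msa_true.width,
            n_columns_kept=filtered.width,
            n_low_entropy=len(low),
            n_core=len(core),
        )
        return filtered, core_msa

    filtered_msa, core_msa = run_stage("conservation", _conservation)

    # -- trees + purity ----------------------------------------------------
    def _trees():
        results = {}
        for tag, m in (("full", filtered_msa), ("core", core_msa)):
            tree = phylogeny.neighbor_joining(phylogeny.p_distance(m))
            phylogeny.write_newick(tree, out / f"tree_{tag}.nwk")
            results[tag] = tree
        with open(out / "purity.tsv", "w") as h:
            h.write("tree\tlabel_set\tk\tpurity\n")
            for tag, tree in results.items():
                for label_name, labels in (
                    ("function", truth.function_labels),
                    ("kingdom", truth.kingdom_labels),
                ):
                    purity = phylogeny.clade_purity(tree, labels, config.purity_k)
                    h.write(f"{tag}\t{label_name}\t{config.purity_k}\t{purity:.4f}\n")
                    report.setdefault("purity", {})[f"{tag}_{label_name}"] = purity
        log_stage("trees", n_trees=len(results), purity_k=config.purity_k)

    run_stage("trees", _trees)

    log_handle.close()
    with open(out / "report.json", "w") as h:
        json.dump(report, h, indent=2, sort_keys=True)
    return report
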