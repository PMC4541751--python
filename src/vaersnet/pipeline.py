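"""End-to-end pipeline: ingest → PRR → networks → similarity → exports.

One batch run over a report corpus (raw VAERS-style tables, a normalised
flat file, an in-memory ReportSet, or a synthetic configuration) producing
deterministic text artifacts: the association summary TSV, the RDF graph,
per-stratum GraphML networks, the network-characteristics table, vaccine
similarity matrices, Newick dendrograms and the female/male PCC density
comparison — plus a manifest of paths and content checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import association_network as an
from . import bipartite_similarity as bs
from . import disproportionality as dp
from . import rdf_export as rdf
from . import synthetic as syn
from . import vaers_io as vio

logger = logging.getLogger(__name__)

ALL_STRATA = ("years", "F", "M", "overall")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """What to run and where to write it.

    Exactly one input source must be given: ``input_tables`` (DATA, VACCINE,
    SYMPTOMS paths), ``normalized_input`` (flat CSV), ``reports`` (in
    memory), or ``synthetic``.  ``seed`` overrides the synthetic config's
    seed when provided.
    """

    out_dir: Path
    input_tables: Optional[tuple[Path, Path, Path]] = None
    normalized_input: Optional[Path] = None
    reports: Optional[vio.ReportSet] = None
    synthetic: Optional[syn.SyntheticConfig] = None
    threshold: float = 1.0
    strata: Sequence[str] = ALL_STRATA
    linkage: str = "average"
    seed: Optional[int] = None

    def validate(self) -> None:
        sources = [
            self.input_tables is not None,
            self.normalized_input is not None,
            self.reports is not None,
            self.synthetic is not None,
        ]
        if sum(sources) != 1:
            raise ValueError("exactly one input source must be configured")
        if self.threshold <= 0:
            raise ValueError("PRR threshold must be positive")
        unknown = set(self.strata) - set(ALL_STRATA)
        if unknown:
            raise ValueError(f"unknown strata {sorted(unknown)}; allowed: {ALL_STRATA}")


@dataclass
class RunManifest:
    """Artifact paths, sha256 checksums and stage log for one pipeline run."""

    artifacts: dict[str, dict[str, str]] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)
    partial: bool = False

    def add(self, name: str, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.artifacts[name] = {"path": str(path), "sha256": digest}

    def checksums(self) -> dict[str, str]:
        return {name: info["sha256"] for name, info in self.artifacts.items()}

    def to_json(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2), encoding="utf-8")


def _load_reports(config: PipelineConfig) -> vio.ReportSet:
    if config.reports is not None:
        return config.reports
    if config.normalized_input is not None:
        return vio.read_normalized(config.normalized_input)
    if config.input_tables is not None:
        d, v, s = config.input_tables
        return vio.read_reports(d, v, s)
    assert config.synthetic is not None
    sc = config.synthetic
    if config.seed is not None:
        sc = dataclasses.replace(sc, seed=config.seed)
    reports, _ = syn.generate_reports(sc)
    return reports


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages; identical config + seed gives identical checksums."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest()
    stage = "load"

    def log(msg: str) -> None:
        logger.info(msg)
        manifest.log.append(msg)

    try:
        reports = _load_reports(config)
        log(f"load: {len(reports)} reports ({reports.provenance})")
        manifest.stage_counts["reports"] = len(reports)

        stage = "summarize"
        records, ctx = dp.count_pairs(reports)
        dp.compute_prrs(records, ctx)
        total_mentions = sum(r.n_pair_total for r in records)
        log(f"summarize: {total_mentions} pair mentions, {len(records)} distinct pairs")
        manifest.stage_counts["pair_mentions"] = total_mentions
        manifest.stage_counts["distinct_pairs"] = len(records)
        assoc_path = out / "associations.tsv"
        dp.associations_to_frame(records).to_csv(
            assoc_path, sep="\t", index=False, float_format="%.10g"
        )
        manifest.add("associations_tsv", assoc_path)

        stage = "rdf"
        graph = rdf.to_rdf(records)
        rdf_path = out / "associations.nt"
        rdf.write_ntriples(graph, rdf_path)
        log(f"rdf: {len(graph)} triples")
        manifest.add("rdf", rdf_path)

        stage = "network"
        strata: list[tuple[str, dp.Stratum]] = []
        if "years" in config.strata:
            strata += [(str(y), ("year", y)) for y in ctx.years()]
        if "F" in config.strata:
            strata.append(("Female", ("sex", "F")))
        if "M" in config.strata:
            strata.append(("Male", ("sex", "M")))
        if "overall" in config.strata:
            strata.append(("Overall", "overall"))

        rows: list[tuple[str, an.NetworkMetrics]] = []
        nets: dict[str, an.BipartiteNetwork] = {}
        for label, stratum in strata:
            sig = dp.significant_associations(records, stratum, config.threshold)
            net = an.build_network(sig)
            nets[label] = net
            rows.append((label, an.network_metrics(net)))
            gpath = out / f"network_{label}.graphml"
            an.write_graphml(net, gpath)
            manifest.add(f"network_{label}_graphml", gpath)
            log(f"network[{label}]: {len(sig)} significant pairs, "
                f"{net.n_node} nodes, {net.n_link} links")
        manifest.stage_counts["significant_overall"] = (
            nets["Overall"].n_link if "Overall" in nets else 0
        )
        metrics_path = out / "network_metrics.tsv"
        an.metrics_table_to_tsv(rows, metrics_path)
        manifest.add("metrics_tsv", metrics_path)

        stage = "similarity"
        sims: dict[str, bs.SimilarityMatrix] = {}
        for label in ("Female", "Male", "Overall"):
            net = nets.get(label)
            if net is None:
                continue
            if len(net.vaccine_nodes) < 2:
                log(f"similarity[{label}]: skipped (<2 vaccines)")
                continue
            sim = bs.similarity_matrix(net, project_onto="vaccine")
            sims[label] = sim
            spath = out / f"similarity_{label}.tsv"
            sim.to_tsv(spath)
            manifest.add(f"similarity_{label}_tsv", spath)
            tree = bs.cluster_vaccines(sim, method=config.linkage)
            npath = out / f"dendrogram_{label}.nwk"
            npath.write_text(tree.to_newick() + "\n", encoding="utf-8")
            manifest.add(f"dendrogram_{label}_newick", npath)

        stage = "compare"
        if "Female" in sims and "Male" in sims:
            comparison = bs.compare_strata(sims["Female"], sims["Male"])
            dpath = out / "pcc_density_female_male.tsv"
            density = comparison.density.rename(
                columns={"count_a": "count_f", "count_b": "count_m"}
            )
            density.to_csv(dpath, sep="\t", index=False)
            manifest.add("density_tsv", dpath)
            manifest.stage_counts["common_vaccines"] = len(comparison.common_labels)
            log(f"compare: KS distance {comparison.ks_distance:.4f} over "
                f"{len(comparison.common_labels)} common vaccines")

        stage = "manifest"
        manifest.to_json(out / "manifest.json")
        return manifest
    except Exception as exc:
        manifest.partial = True
        try:
            manifest.to_json(out / "manifest.json")
        except OSError:
            pass
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
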