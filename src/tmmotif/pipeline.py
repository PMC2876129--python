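"""End-to-end orchestration: structures -> fragments -> clusters -> motifs -> stats.

The workflow mirrors the six-step motif-library construction: dataset
filtering, fragment generation per membrane region and window length,
hierarchical clustering on a structural measure (hydrogen-bond patterns or
torsion profiles) with the structural tree cut, Prosite-style pattern
induction at 80% coverage, a sequence-based re-clustering fallback (patterns
induced at 100% coverage) for clusters without an induced motif, motif
statistics against TM/globular databases, novelty filtering against a
pattern library, and redundancy grouping by hit-set overlap.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from tmmotif.cluster import ClusterSet, average_linkage, cut_sequence_tree, cut_structural_tree
from tmmotif.fragments import Fragment, make_fragments
from tmmotif.metrics import (
    HBWeights,
    dist_hb_matrix,
    dist_sequence_matrix,
    dist_torsion_matrix,
)
from tmmotif.motifs import RegexMotif, group_redundant, induce_pattern, motif_to_string
from tmmotif.patterncmp import novelty_filter
from tmmotif.stats import MotifReport, build_motif_report
from tmmotif.structio import ChainModel, filter_dataset

logger = logging.getLogger("tmmotif")


@dataclass
class PipelineConfig:
    lengths: tuple[int, ...] = (5, 7)
    regions: tuple[str, ...] = ("Helix core", "Cytoplasmic", "Extracellular", "Reentrant", "Interface")
    measure: str = "torsion"  # hbond | torsion
    max_resolution: float = 3.5
    identity_threshold: float = 0.90
    rmsd_threshold: float = 1.5
    lambda_tradeoff: float = 2.0
    min_cluster_size: int = 2
    seq_min_size: int = 5
    min_match_structural: float = 0.8
    min_match_sequence: float = 1.0
    max_set_size: int = 4
    novelty_cutoff: float = 0.86
    n_perm: int = 100
    alpha_perm: float = 0.05
    hb_weights: HBWeights = field(default_factory=HBWeights)
    seed: int = 0


@dataclass
class PipelineResult:
    motifs: list[RegexMotif]
    reports: list[MotifReport]
    cluster_census: list[dict]
    groups: list
    manifest: dict


def _distance_matrix(frags: list[Fragment], cfg: PipelineConfig):
    if cfg.measure == "hbond":
        return dist_hb_matrix(frags, cfg.hb_weights)
    if cfg.measure == "torsion":
        return dist_torsion_matrix(frags)
    raise ValueError(f"unknown measure {cfg.measure!r}")


def derive_motifs(
    frags: list[Fragment], cfg: PipelineConfig
) -> tuple[list[RegexMotif], ClusterSet | None, list[dict]]:
    """Cluster one (region, length) fragment group and induce motifs.

    Structural clustering first; clusters whose members yield no pattern at
    the 80% coverage level fall back to sequence-based clustering with
    patterns induced at 100% coverage.
    """
    if cfg.measure == "torsion":
        frags = [f for f in frags if f.has_full_torsions()]
    if len(frags) < 2:
        return [], None, []
    by_id = {f.frag_id: f for f in frags}
    dend = average_linkage(_distance_matrix(frags, cfg))
    cset = cut_structural_tree(dend, frags, cfg.rmsd_threshold, cfg.lambda_tradeoff)
    motifs: list[RegexMotif] = []
    provenance: list[dict] = []
    for k, cluster in enumerate(cset.clusters):
        if len(cluster) < max(cfg.min_cluster_size, 2):
            continue
        seqs = [by_id[i].sequence for i in cluster]
        motif = induce_pattern(seqs, cfg.min_match_structural, cfg.max_set_size)
        if motif is not None:
            motifs.append(motif)
            provenance.append({"cluster": k, "route": "structural", "size": len(cluster)})
            continue
        # sequence-based fallback for clusters without an induced motif
        members = [by_id[i] for i in cluster]
        if len(members) < 2:
            continue
        sdend = average_linkage(dist_sequence_matrix(members))
        scset = cut_sequence_tree(sdend, cfg.seq_min_size)
        for sk, scluster in enumerate(scset.clusters):
            if len(scluster) < 2:
                continue
            sseqs = [by_id[i].sequence for i in scluster]
            smotif = induce_pattern(sseqs, cfg.min_match_sequence, cfg.max_set_size)
            if smotif is not None:
                motifs.append(smotif)
                provenance.append(
                    {"cluster": k, "subcluster": sk, "route": "sequence", "size": len(scluster)}
                )
    return motifs, cset, provenance


def run_pipeline(
    chains: list[ChainModel],
    cfg: PipelineConfig | None = None,
    tm_db: list[tuple[str, str]] | None = None,
    glob_db: list[tuple[str, str]] | None = None,
    go_annotations: list[tuple[str, str]] | None = None,
    library: list[RegexMotif] | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full motif-library workflow on a set of annotated chains."""
    cfg = cfg or PipelineConfig()
    chains = filter_dataset(chains, cfg.max_resolution, cfg.identity_threshold)
    logger.info("dataset: %d chains after filtering", len(chains))

    frags: list[Fragment] = []
    for chain in chains:
        frags.extend(make_fragments(chain, lengths=cfg.lengths))
    logger.info("fragments: %d", len(frags))

    motifs: list[RegexMotif] = []
    census: list[dict] = []
    seen: set[str] = set()
    for region in cfg.regions:
        for length in cfg.lengths:
            group = [f for f in frags if f.region == region and f.length == length]
            if len(group) < 2:
                continue
            got, cset, prov = derive_motifs(group, cfg)
            if cset is not None:
                census.append(
                    {
                        "region": region,
                        "length": length,
                        "fragments": len(group),
                        "clusters": len(cset.clusters),
                        "outliers": len(cset.outliers),
                        "largest": cset.largest,
                        "motifs": len(got),
                    }
                )
            for m in got:
                s = motif_to_string(m)
                if s not in seen:
                    seen.add(s)
                    motifs.append(m)

    reports: list[MotifReport] = []
    if tm_db is not None and glob_db is not None:
        for i, m in enumerate(motifs):
            reports.append(
                build_motif_report(
                    m,
                    tm_db,
                    glob_db,
                    go_annotations,
                    n_perm=cfg.n_perm,
                    seed=cfg.seed * 1009 + i,
                )
            )

    if library:
        verdicts = novelty_filter(motifs, library, cfg.novelty_cutoff)
        for rep, v in zip(reports, verdicts):
            rep.novelty = v.verdict

    groups = group_redundant(motifs, tm_db, 0.8) if tm_db and motifs else []

    manifest = {
        "n_chains": len(chains),
        "n_fragments": len(frags),
        "n_motifs": len(motifs),
        "n_significant": sum(1 for r in reports if r.p_perm < cfg.alpha_perm),
        "n_groups": len(groups),
        "census": census,
        "motifs": [motif_to_string(m) for m in motifs],
        "seed": cfg.seed,
    }
    result = PipelineResult(motifs, reports, census, groups, manifest)
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "motifs.txt").write_text(
        "".join(motif_to_string(m) + "\n" for m in result.motifs)
    )
    rows = [
        "motif\tN_M\tN_GLOB\tp_perm\tp_empirical\todds_ratio\tfp_rate"
        "\tspecificity_p\tabundance\tspecificity\tnovelty"
    ]
    for r in result.reports:
        rows.append(
            f"{motif_to_string(r.motif)}\t{r.n_m}\t{r.n_glob}\t{r.p_perm:.4g}"
            f"\t{r.p_empirical:.4g}\t{r.odds:.4g}\t{r.fp_rate:.4g}\t{r.specificity_p:.4g}"
            f"\t{r.abundance_class}\t{r.specificity_class}\t{r.novelty or ''}"
        )
    (outdir / "reports.tsv").write_text("\n".join(rows) + "\n")
    census_rows = ["region\tlength\tfragments\tclusters\toutliers\tlargest\tmotifs"]
    for c in result.cluster_census:
        census_rows.append(
            f"{c['region']}\t{c['length']}\t{c['fragments']}\t{c['clusters']}"
            f"\t{c['outliers']}\t{c['largest']}\t{c['motifs']}"
        )
    (outdir / "cluster_census.tsv").write_text("\n".join(census_rows) + "\n")
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=1))
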