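"""End-to-end orchestration of the two analysis arms and their integration.

``run_pipeline`` executes, in order: ADME screening → target filtering →
pathway annotation (systems-pharmacology arm); spectral preprocessing →
OPLS-DA → correlation-loading biomarker selection → univariate statistics →
pathway enrichment (metabonomics arm); and finally the pathway-overlap
integration with reverse mapping to herbs, compounds, and proteins.  Every
stage writes its table into the run directory, and a summary table plus the
resolved configuration are written at the end.

Inputs either come from files (see ``REQUIRED_INPUTS``) or are simulated
with the synthetic generators under the run's seed.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment as enr
from . import integration as integ
from .chemometrics import OPLSDA, ScalingSpec, select_biomarkers
from .config import PipelineConfig
from .io import read_spectra, read_table, write_spectra, write_table
from .library import PathwayLibrary, read_library, write_library
from .nmr import BucketSpec, bucket_samples
from .screening import (
    DEFAULT_WHITELIST,
    ScreenCriteria,
    Whitelist,
    active_table,
    build_herb_compound_network,
    records_from_table,
    screen_compounds,
)
from .stats import compare_groups, comparison_table
from .synthetic import (
    SyntheticConfig,
    _annotated_kegg_ids,
    generate_compound_table,
    generate_spectra,
    generate_target_and_pathway_library,
    template_bucket_map,
)
from .targets import TargetHit, annotate_pathways, filter_targets, protein_support

logger = logging.getLogger(__name__)

REQUIRED_INPUTS = (
    "compound_table",
    "hits",
    "library_members",
    "spectra_manifest",
    "bucket_map",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _bucket_map_from_table(frame: pd.DataFrame) -> dict[str, list[tuple[float, float]]]:
    out: dict[str, list[tuple[float, float]]] = {}
    for _, row in frame.iterrows():
        out.setdefault(row["metabolite"], []).append((float(row["low"]), float(row["high"])))
    return out


def _metabolite_levels(matrix, bucket_map) -> pd.DataFrame:
    """Per-sample metabolite levels: summed normalized buckets per window set."""
    ppm = matrix.ppm
    cols = {}
    for name, windows in bucket_map.items():
        mask = np.zeros(ppm.shape, dtype=bool)
        for lo, hi in windows:
            mask |= (ppm >= lo) & (ppm <= hi)
        if mask.any():
            cols[name] = matrix.X()[:, mask].sum(axis=1)
    return pd.DataFrame(cols, index=matrix.values.index)


def run_pipeline(
    config: PipelineConfig,
    outdir,
    inputs: dict | None = None,
    simulate: bool = False,
) -> Path:
    """Run both arms and the integration; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    synth_truth = None

    # ------------------------------------------------------------------ inputs
    if simulate:
        scfg = SyntheticConfig(
            seed=config.seed,
            n_per_group=config.n_per_group,
            noise_cv=config.noise_cv,
            planted_overlap_names=config.planted_overlap_names,
        )
        compound_table, truth0 = generate_compound_table(scfg)
        hits_table, library, synth_truth = generate_target_and_pathway_library(scfg, truth0)
        spectra, spec_truth = generate_spectra(scfg)
        bucket_map = template_bucket_map()
        whitelist = Whitelist()
        write_spectra(spectra, outdir / "spectra")
        write_table(compound_table, outdir / "compound_table.tsv")
        write_table(hits_table, outdir / "target_hits.tsv")
        write_library(library, outdir / "library_members.tsv", outdir / "library_edges.tsv")
    else:
        inputs = inputs or {}
        missing = [k for k in REQUIRED_INPUTS if k not in inputs]
        if missing:
            raise PipelineError("inputs", f"missing required input(s): {', '.join(missing)}")
        compound_table = read_table(inputs["compound_table"])
        hits_table = read_table(inputs["hits"])
        library = read_library(
            inputs["library_members"], inputs.get("library_edges")
        )
        spectra = read_spectra(inputs["spectra_manifest"])
        bucket_map = _bucket_map_from_table(read_table(inputs["bucket_map"]))
        whitelist = (
            Whitelist.from_file(inputs["whitelist"])
            if "whitelist" in inputs
            else DEFAULT_WHITELIST
        )
    literature_pathways: list[str] = []
    if inputs and "literature_pathways" in inputs:
        with open(inputs["literature_pathways"]) as fh:
            literature_pathways = [ln.strip() for ln in fh if ln.strip()]

    # ------------------------------------------------------- arm 1: screening
    criteria = ScreenCriteria(config.ob_min, config.bbb_min, config.dl_min, config.hl_min)
    records = records_from_table(compound_table)
    active = screen_compounds(records, criteria, whitelist)
    write_table(active_table(active), outdir / "active_compounds.tsv")
    _, herb_counts = build_herb_compound_network(active)
    logger.info("screening: %d/%d compounds retained", len(active), len(records))

    hits = [
        TargetHit(str(r.compound_id), str(r.protein_id), int(r.fit_rank), float(r.z_score))
        for r in hits_table.itertuples(index=False)
    ]
    active_ids = {r.compound_id for r in active}
    kept_hits = [h for h in filter_targets(hits, config.top_n, config.z_min) if h.compound_id in active_ids]
    proteins = protein_support(kept_hits)
    write_table(proteins, outdir / "filtered_targets.tsv")
    syspharm = annotate_pathways(proteins["protein_id"], library, literature_pathways)
    write_table(syspharm, outdir / "syspharm_pathways.tsv")

    # ---------------------------------------------------- arm 2: metabonomics
    spec = BucketSpec(
        width=config.bucket_width,
        region=tuple(config.region),
        exclusions=tuple(tuple(e) for e in config.exclusions),
    )
    matrix = bucket_samples(spectra, spec)
    matrix.values.to_csv(outdir / "bucket_matrix.tsv", sep="\t")

    scaling = ScalingSpec(scaling=config.scaling)
    case, ref = config.contrasts[0]
    model = OPLSDA.from_bucket_matrix(matrix, case, ref, n_orth=config.n_orth, scaling=scaling)
    res = model.fit()
    res.cross_validate(folds=config.cv_folds, seed=config.seed)
    write_table(res.summary(), outdir / "oplsda_summary.tsv")
    threshold_n = config.threshold_n or config.n_per_group
    loadings = res.correlation_loadings(threshold_n=threshold_n, alpha=config.alpha)
    write_table(loadings.table(), outdir / "correlation_loadings.tsv")
    biomarkers = select_biomarkers(loadings, bucket_map)
    write_table(biomarkers, outdir / "biomarkers.tsv")
    logger.info("biomarkers: %d metabolites selected", len(biomarkers))

    levels = _metabolite_levels(matrix, bucket_map)
    rows = compare_groups(levels, matrix.groups, contrasts=tuple(tuple(c) for c in config.contrasts))
    write_table(comparison_table(rows), outdir / "univariate_stats.tsv")

    selected = [m for m in biomarkers["metabolite"] if m != "unassigned"]
    kegg = _annotated_kegg_ids(selected)
    query = sorted(set(kegg.values()) & set(library.compound_universe))
    table_rows = enr.build_enrichment_table(query, library)
    write_table(enr.enrichment_table(table_rows), outdir / "pathway_enrichment.tsv")

    # ------------------------------------------------------------ integration
    significant = [r.name for r in table_rows if r.significant]
    overlapping, non_overlapping = integ.overlap_pathways(
        significant, syspharm["name"].tolist()
    )
    compound_to_proteins: dict[str, set[str]] = {}
    for h in kept_hits:
        compound_to_proteins.setdefault(h.compound_id, set()).add(h.protein_id)
    herb_to_compounds: dict[str, set[str]] = {}
    for r in active:
        for herb in r.herbs:
            herb_to_compounds.setdefault(herb, set()).add(r.compound_id)
    network = integ.reverse_map(
        overlapping, library.protein_to_pathways(), compound_to_proteins, herb_to_compounds
    ) if overlapping else integ.TripartiteNetwork()
    if network.graph.number_of_nodes():
        integ.export_network(network, outdir / "integration_network.sif", "sif")
        integ.export_network(network, outdir / "integration_network.graphml", "graphml")

    summary = pd.DataFrame(
        [
            {"quantity": "compounds_screened", "value": len(records)},
            {"quantity": "active_compounds", "value": len(active)},
            {"quantity": "retained_target_hits", "value": len(kept_hits)},
            {"quantity": "distinct_proteins", "value": len(proteins)},
            {"quantity": "syspharm_pathways", "value": len(syspharm)},
            {"quantity": "buckets", "value": matrix.values.shape[1]},
            {"quantity": "biomarkers", "value": len(selected)},
            {"quantity": "significant_pathways", "value": len(significant)},
            {"quantity": "overlapping_pathways", "value": "; ".join(sorted(overlapping))},
            {"quantity": "non_overlapping_pathways", "value": "; ".join(sorted(non_overlapping))},
            {"quantity": "network_herbs", "value": len(network.nodes_in_tier("herb"))},
            {"quantity": "network_compounds", "value": len(network.nodes_in_tier("compound"))},
            {"quantity": "network_proteins", "value": len(network.nodes_in_tier("protein"))},
        ]
    )
    write_table(summary, outdir / "summary.tsv")
    config.to_yaml(outdir / "resolved_config.yaml")
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    return outdir
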