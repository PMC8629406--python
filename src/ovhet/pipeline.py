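"""End-to-end orchestration: (simulate |) load -> filter -> classify ->
heterogeneity statistics -> clustering/trees -> spectra.

Every stage writes its result as TSV into the output directory; trees are
written as one Newick file per patient. A run manifest records the seed, a
hash of the effective configuration, library versions and per-stage record
counts, and a rerun with identical configuration and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import (
    annotate_effects,
    category_table,
    label_concordant_patient,
    label_sharing_cohort,
)
from .cluster_phylo import (
    af_distance,
    build_af_matrix,
    build_patient_tree,
    cluster_samples,
    tree_leaf_pairs,
)
from .clonesim import SimulationConfig, reference_cohort_layout, simulate_cohort
from .hetstats import (
    concordance_heatmap_matrix,
    leaf_pair_similarity,
    mutational_burden,
    per_gene_counts,
    per_pathway_counts,
)
from .somatic_filter import FilterConfig, apply_somatic_filters, filter_summary
from .spectrum import compare_spectra, spectra_frame, spectrum_by_stage
from .variant_io import (
    VariantCall,
    read_gene_panel,
    read_sample_sheet,
    read_variant_table,
    write_newick,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for diagnosis."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run.

    Either the three input paths are set, or ``simulate`` is True and a
    cohort is generated inline from ``sim`` with ``seed``.
    """

    out_dir: str = "ovhet_out"
    seed: int = 0
    # inputs
    variants_path: str | None = None
    samples_path: str | None = None
    panel_bed: str | None = None
    pathways_path: str | None = None
    simulate: bool = False
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    use_reference_layout: bool = False
    # analysis toggles
    filter: FilterConfig = field(default_factory=FilterConfig)
    exclude_synonymous: bool = True
    metric: str = "euclidean"
    linkage: str = "average"
    outgroup_id: str = "OVCAR-8"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["filter"] = {k: v for k, v in asdict(self.filter).items()
                       if k != "extra_predicates"}
        return d


def _config_hash(cfg: RunConfig) -> str:
    text = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages; returns the manifest (also written to the output dir)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "ovhet_version": __version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "stages": {},
    }

    # ---- stage: inputs -----------------------------------------------------
    stage = "inputs"
    try:
        if cfg.simulate:
            layouts = reference_cohort_layout(cfg.sim.n_patients) if cfg.use_reference_layout else None
            calls_by_sample, metas, truths, panel = simulate_cohort(
                cfg.sim, cfg.seed, layouts=layouts
            )
        else:
            if not (cfg.variants_path and cfg.samples_path and cfg.panel_bed
                    and cfg.pathways_path):
                raise ValueError("input paths missing and simulate not enabled")
            raw = read_variant_table(cfg.variants_path)
            metas = read_sample_sheet(cfg.samples_path)
            panel = read_gene_panel(cfg.panel_bed, cfg.pathways_path)
            truths = None
            calls_by_sample = {}
            for c in raw:
                calls_by_sample.setdefault(c.sample_id, []).append(c)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    midx = {m.sample_id: m for m in metas}
    manifest["stages"][stage] = {
        "n_samples": len(metas),
        "n_raw_calls": sum(len(v) for v in calls_by_sample.values()),
    }

    # ---- stage: filter -----------------------------------------------------
    stage = "filter"
    try:
        blood_of = {m.patient_id: m.sample_id for m in metas if m.role == "blood"}
        passing_by_sample: dict[str, list[VariantCall]] = {}
        audit_rows = []
        for m in metas:
            if m.role == "control":
                # unrelated control line: no matched normal, used only as
                # the phylogeny outgroup; calls pass through unfiltered
                passing_by_sample[m.sample_id] = list(calls_by_sample.get(m.sample_id, []))
                continue
            if m.role != "tumor":
                continue
            blood_id = blood_of.get(m.patient_id)
            if blood_id is None:
                raise ValueError(f"no matched blood for patient {m.patient_id}")
            result = apply_somatic_filters(
                calls_by_sample.get(m.sample_id, []),
                calls_by_sample.get(blood_id, []),
                cfg.filter,
            )
            passing_by_sample[m.sample_id] = result.passing
            for call, reason in result.rejected:
                audit_rows.append({
                    "sample_id": call.sample_id, "chrom": call.locus.chrom,
                    "pos": call.locus.pos, "ref": call.locus.ref,
                    "alt": call.locus.alt, "depth": call.depth,
                    "alt_reads": call.alt_reads, "af": f"{call.af:.6f}",
                    "reason": reason,
                })
        audit = pd.DataFrame(
            audit_rows,
            columns=["sample_id", "chrom", "pos", "ref", "alt", "depth",
                     "alt_reads", "af", "reason"],
        )
        audit.to_csv(out / "filter_audit.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    n_pass = sum(len(v) for v in passing_by_sample.values())
    manifest["stages"][stage] = {
        "n_passing": n_pass,
        "n_rejected": len(audit_rows),
        "reasons": filter_summary(
            [(None, r["reason"]) for r in audit_rows]  # type: ignore[list-item]
        ),
    }

    # ---- stage: classify ---------------------------------------------------
    stage = "classify"
    try:
        tumor_calls = [
            c for s, calls in sorted(passing_by_sample.items())
            for c in calls
            if midx[s].role == "tumor"
        ]
        tumor_calls = annotate_effects(tumor_calls)
        passing_by_sample = {
            s: (annotate_effects(calls) if midx[s].role == "tumor" else calls)
            for s, calls in passing_by_sample.items()
        }
        sharing = label_sharing_cohort(tumor_calls, metas)
        cat = category_table(tumor_calls, metas, sharing)
        cat.to_tsv(out / "category_table.tsv")

        patient_labels = {}
        patients = sorted({m.patient_id for m in metas if m.role == "tumor"})
        for pid in patients:
            p_samples = {m.sample_id for m in metas
                         if m.patient_id == pid and m.role == "tumor"}
            has_ovary = any(
                midx[s].is_primary_tumor and midx[s].site == "ovary" for s in p_samples
            )
            has_sync = any(
                midx[s].is_primary_tumor and midx[s].site != "ovary" for s in p_samples
            )
            if not (has_ovary and has_sync):
                continue
            p_calls = [c for c in tumor_calls if c.sample_id in p_samples]
            patient_labels[pid] = label_concordant_patient(p_calls, metas)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    manifest["stages"][stage] = {
        "n_loci": len(sharing),
        "n_shared": sum(1 for v in sharing.values() if v == "shared"),
        "grand_total": cat.grand_total,
        "shared_fraction_pct": cat.shared_fraction_pct,
    }

    # ---- stage: hetstats ---------------------------------------------------
    stage = "hetstats"
    try:
        burden = mutational_burden(tumor_calls, metas)
        burden.to_csv(out / "burden.tsv", sep="\t")
        gene_counts = per_gene_counts(tumor_calls, panel, metas)
        gene_counts.to_csv(out / "per_gene_counts.tsv", sep="\t")
        pw_counts, pw_tests = per_pathway_counts(gene_counts, panel)
        pw_counts.to_csv(out / "per_pathway_counts.tsv", sep="\t")
        pw_tests.to_csv(out / "pathway_tests.tsv", sep="\t", float_format="%.6g")
        conc_matrix = concordance_heatmap_matrix(patient_labels, panel)
        conc_matrix.to_csv(out / "concordance_matrix.tsv", sep="\t")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    manifest["stages"][stage] = {
        "n_tumor_samples": int(len(burden)),
        "total_burden": int(burden["total"].sum()),
        "n_concordant": int(conc_matrix.to_numpy().sum()),
    }

    # ---- stage: trees ------------------------------------------------------
    stage = "trees"
    try:
        trees_dir = out / "trees"
        trees_dir.mkdir(exist_ok=True)
        control_calls = passing_by_sample.get(cfg.outgroup_id, [])
        trees = {}
        similarity_rows = []
        for pid in sorted({m.patient_id for m in metas if m.role == "tumor"}):
            p_metas = [m for m in metas
                       if m.patient_id == pid and m.role == "tumor"]
            if len(p_metas) < 2 or not control_calls:
                continue
            p_calls = [c for m in p_metas for c in passing_by_sample[m.sample_id]]
            mat = build_af_matrix(
                p_calls + control_calls,
                exclude_synonymous=cfg.exclude_synonymous,
                sample_ids=sorted(m.sample_id for m in p_metas) + [cfg.outgroup_id],
            )
            tree = build_patient_tree(af_distance(mat, cfg.metric), cfg.outgroup_id)
            trees[pid] = tree
            write_newick(tree, trees_dir / f"{pid}.nwk")

            universe = {c.locus for c in p_calls}
            called = {m.sample_id: {c.locus for c in passing_by_sample[m.sample_id]}
                      for m in p_metas}
            for a, b in tree_leaf_pairs(tree, exclude=[cfg.outgroup_id]):
                triple = leaf_pair_similarity(a, b, called, universe)
                similarity_rows.append(triple.as_row())
        sim_table = pd.DataFrame(
            similarity_rows,
            columns=["sample_a", "sample_b", "Concordant mutations",
                     "Private mutations", "Wt"],
        )
        sim_table.to_csv(out / "similarity.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    manifest["stages"][stage] = {
        "n_trees": len(trees),
        "n_leaf_pairs": len(similarity_rows),
    }

    # ---- stage: clustering -------------------------------------------------
    stage = "clustering"
    try:
        cohort_mat = build_af_matrix(
            tumor_calls, exclude_synonymous=cfg.exclude_synonymous,
            sample_ids=sorted({c.sample_id for c in tumor_calls}),
        )
        cluster = None
        if len(cohort_mat.sample_ids) >= 2:
            cluster = cluster_samples(cohort_mat, cfg.metric, cfg.linkage)
            pd.DataFrame({
                "sample_id": cluster.sample_ids,
                "cluster_k2": [cluster.flat_clusters[s] for s in cluster.sample_ids],
                "dendrogram_position": [cluster.sample_order.index(s)
                                        for s in cluster.sample_ids],
            }).to_csv(out / "cluster_samples.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    manifest["stages"][stage] = {
        "n_samples": len(cohort_mat.sample_ids),
        "n_loci": len(cohort_mat.loci),
    }

    # ---- stage: spectrum ---------------------------------------------------
    stage = "spectrum"
    try:
        spectra = spectrum_by_stage(tumor_calls, metas)
        sp = spectra_frame(spectra)
        if spectra["pre_chemo"].total > 0 and spectra["post_chemo"].total > 0:
            stat, p, dof = compare_spectra(spectra["pre_chemo"], spectra["post_chemo"])
            manifest["stages"][stage] = {
                "chi2": round(stat, 6), "pvalue": round(p, 6), "dof": dof,
            }
        else:
            manifest["stages"][stage] = {"chi2": None, "pvalue": None, "dof": None}
        sp.to_csv(out / "spectra.tsv", sep="\t")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    manifest["stages"][stage].update(
        {name: s.total for name, s in sorted(spectra.items())}
    )

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
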