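"""End-to-end driver: discovery filters -> homology tiers -> localization ->
target prediction -> gene age -> enrichment and expression statistics ->
copy-number scan, with recovery scoring against a world's truth manifest.

Permutation sizes default to 99 shuffles for the fold test and 149 for the
target-site null — the smallest grids that can resolve the 0.05 and 0.01
retention thresholds with headroom — so a six-species world runs end to
end in seconds while the dedicated calibration tests probe the permutation
machinery at finer resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import discovery, gene_age, homology, localization, phylo_stats, stats, targets
from .synthetic_data import World

logger = logging.getLogger("beemir")

DEFAULT_RANDFOLD_SHUFFLES = 99
DEFAULT_TARGET_PERM = 149


@dataclass
class SpeciesResult:
    species_id: str
    candidates: list[discovery.MiRCandidate]
    retained: list[discovery.MiRCandidate]
    catalog: list[homology.MatureMiR]
    localization: localization.LocalizationSummary
    utrs: list[targets.UtrProxy]
    target_predictions: targets.TargetPredictions | None = None
    gene_ages: list[gene_age.GeneAge] = field(default_factory=list)
    enrichment: stats.EnrichmentResult | None = None
    ttest: tuple[float, float, float] | None = None
    chi2: tuple[float, float] | None = None


@dataclass
class PipelineResult:
    species: dict[str, SpeciesResult]
    calls: list[homology.HomologyCall]
    copy_scan: pd.DataFrame
    summary: pd.DataFrame


def run_pipeline(
    world: World,
    rng: np.random.Generator | None = None,
    n_randfold_shuffles: int = DEFAULT_RANDFOLD_SHUFFLES,
    n_target_perm: int = DEFAULT_TARGET_PERM,
    predict_targets_for: str = "lineage_specific",
) -> PipelineResult:
    """Run every stage of the analysis on a (synthetic or loaded) world."""
    if rng is None:
        rng = np.random.default_rng()
    ka_params = homology.solve_karlin_altschul()

    per_species: dict[str, SpeciesResult] = {}
    catalogs: dict[str, list[homology.MatureMiR]] = {}
    premir_seqs: dict[str, dict[str, str]] = {}

    for sp in world.species:
        reads = discovery.qc_reads(world.reads[sp])
        mapped = discovery.map_reads_exact(reads, world.genomes[sp])
        candidates = [discovery.MiRCandidate(pre) for pre in world.premirs[sp]]
        for cand in candidates:
            discovery.count_support(cand, reads, mapped)
            cand.contaminant_hit = discovery.contaminant_screen(
                cand.pre_mir.sequence, world.contaminants
            )
        discovery.randfold_test_batch(candidates, n_randfold_shuffles, rng)
        retained = discovery.apply_novel_filters(candidates)

        total_reads = max(reads.total_count, 1)
        catalog = [
            homology.MatureMiR(
                id=cand.pre_mir.id,
                species_id=sp,
                sequence=cand.mature_seq,
                expression=1e6 * cand.mature_count / total_reads,
                pre_mir_id=cand.pre_mir.id,
            )
            for cand in retained
        ]
        catalogs[sp] = catalog
        premir_seqs[sp] = {p.id: p.sequence for p in world.premirs[sp]}

        features = world.genomes[sp].genes + world.genomes[sp].repeats
        loc = localization.summarize_localization(
            [c.pre_mir for c in retained], features
        )
        utrs = []
        for feat in world.genomes[sp].genes:
            if feat.kind != "gene":
                continue
            utr = targets.extract_utr_proxy(feat, world.genomes[sp])
            if utr is not None:
                utrs.append(utr)
        per_species[sp] = SpeciesResult(
            species_id=sp, candidates=candidates, retained=retained,
            catalog=catalog, localization=loc, utrs=utrs,
        )

    calls = homology.classify_all(
        catalogs, world.known_mirs, world.genomes, premir_seqs, ka_params
    )
    calls_by_species: dict[str, list[homology.HomologyCall]] = {}
    for call in calls:
        calls_by_species.setdefault(call.species_id, []).append(call)

    summary_rows = []
    for sp in world.species:
        res = per_species[sp]
        sp_calls = calls_by_species.get(sp, [])
        ls_ids = {c.mirna_id for c in sp_calls if c.lineage_specific}

        # expression: lineage-specific vs homologous (log2 RPM + 1)
        expr = {m.id: m.expression for m in res.catalog}
        ls_expr = [expr[i] for i in sorted(ls_ids) if i in expr]
        hom_expr = [
            expr[c.mirna_id] for c in sp_calls
            if not c.lineage_specific and c.mirna_id in expr
        ]
        if len(ls_expr) >= 2 and len(hom_expr) >= 2:
            res.ttest = stats.expression_ttest(ls_expr, hom_expr)

        # intragenic vs intergenic association with lineage specificity
        try:
            res.chi2 = localization.intra_inter_chi2(sp_calls, res.localization.intragenic)
        except ValueError:
            res.chi2 = None

        # targets of lineage-specific miRNAs
        if predict_targets_for == "lineage_specific":
            mirnas = [m for m in res.catalog if m.id in ls_ids]
        else:
            mirnas = list(res.catalog)
        res.target_predictions = targets.predict_targets(
            mirnas, res.utrs, n_perm=n_target_perm, rng=rng
        )

        # gene ages and young-gene enrichment of the predicted targets
        gene_ids = sorted(
            {f.gene_id for f in world.genomes[sp].genes if f.kind == "gene"}
        )
        res.gene_ages = gene_age.assign_gene_ages(
            world.orthogroups, world.ladder, sp, gene_ids
        )
        universe = set(gene_ids)
        young = {g.gene_id for g in res.gene_ages if g.age_label == gene_age.UNIQUE_LABEL}
        target_genes = {g for _m, g in res.target_predictions.gene_pairs}
        if target_genes and young:
            res.enrichment = stats.hypergeom_enrichment(
                target_genes, young, universe, label=f"{sp}:unique_genes"
            )

        summary_rows.append(
            {
                "species": sp,
                "expressed_mirs": len(res.retained),
                "seed_match": sum(c.tier == "seed_match" for c in sp_calls),
                "premir_homolog": sum(c.tier == "premir_homolog" for c in sp_calls),
                "unique": sum(c.tier == "unique" for c in sp_calls),
                "lineage_specific": len(ls_ids),
                "intergenic": res.localization.counts["intergenic"][0],
                "sense_fraction_genic": res.localization.sense_fraction_genic,
                "n_target_genes": len(target_genes),
                "rf": res.enrichment.RF if res.enrichment else float("nan"),
                "rf_p_over": res.enrichment.p_over if res.enrichment else float("nan"),
                "ttest_p": res.ttest[2] if res.ttest else float("nan"),
            }
        )

    copy_scan = phylo_stats.copy_number_scan(
        world.copy_matrix, world.phylogeny, world.sociality
    )
    return PipelineResult(
        species=per_species,
        calls=calls,
        copy_scan=copy_scan,
        summary=pd.DataFrame(summary_rows),
    )


# ---------------------------------------------------------------------------
# recovery scoring against the truth manifest
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    sensitivity: float
    specificity: float
    filter_pass_rate: float
    rf_estimated_mean: float
    rf_realized_mean: float
    rf_abs_error: float
    target_sensitivity: float


def score_against_truth(world: World, result: PipelineResult) -> RecoveryReport:
    """Compare pipeline calls with the planted truth.

    Lineage-specific sensitivity/specificity are computed over planted
    miRNAs that survived the discovery filters (a miRNA the support or
    structure filters legitimately rejected never reaches classification);
    the overall filter pass rate is reported alongside.  Planted-site
    recovery is likewise measured over sites whose miRNA was retained.
    """
    truth = world.truth
    pred_ls = {(c.species_id, c.mirna_id): c.lineage_specific for c in result.calls}
    tp = fn = tn = fp = 0
    n_planted = n_passed = 0
    for sp in world.species:
        for mirna_id, info in truth.mirna_class[sp].items():
            if info["class"] == "decoy":
                continue
            n_planted += 1
            key = (sp, mirna_id)
            if key not in pred_ls:
                continue
            n_passed += 1
            truly_ls = info["class"] == "lineage_specific"
            called_ls = pred_ls[key]
            if truly_ls and called_ls:
                tp += 1
            elif truly_ls:
                fn += 1
            elif called_ls:
                fp += 1
            else:
                tn += 1

    rf_est, rf_real = [], []
    site_hits = site_total = 0
    for sp in world.species:
        res = result.species[sp]
        if res.enrichment is not None:
            rf_est.append(res.enrichment.RF)
            rf_real.append(truth.realized_rf[sp])
        retained_ids = {c.pre_mir.id for c in res.retained}
        pairs = res.target_predictions.gene_pairs if res.target_predictions else set()
        for site in truth.planted_sites[sp]:
            if site.mirna_id not in retained_ids:
                continue
            site_total += 1
            if (site.mirna_id, site.gene_id) in pairs:
                site_hits += 1

    return RecoveryReport(
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        filter_pass_rate=n_passed / n_planted if n_planted else float("nan"),
        rf_estimated_mean=float(np.mean(rf_est)) if rf_est else float("nan"),
        rf_realized_mean=float(np.mean(rf_real)) if rf_real else float("nan"),
        rf_abs_error=(
            abs(float(np.mean(rf_est)) - float(np.mean(rf_real)))
            if rf_est else float("nan")
        ),
        target_sensitivity=site_hits / site_total if site_total else float("nan"),
    )
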