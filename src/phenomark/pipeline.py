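"""End-to-end orchestration: raw tables -> profiles -> classifiers -> biomarkers.

These helpers chain the library modules the way the analysis scripts and
the acceptance checks use them: assign ASVs (MTA + genome mappings) from
an alignment-hit table, build genus-level taxonomy features and CPI/PAD
phenotype profiles per cohort, run the classifier variant suite for one
predictor set x contrast, and distil stable predictors and their PDP form
labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from . import biomarkers, ml, mta, profiles, simulate, trees
from .reference import BinaryPhenotypeMatrix, ReferenceCollection, sequence_genome_id

#: read-depth cutoff (strict >) applied before profiling
DEFAULT_MIN_READS = 15000


@dataclass
class AssignmentSet:
    """Per-ASV MTA and genome mappings derived from one hit table."""

    mtas: dict[str, mta.MultiTaxonomicAssignment]
    mappings: dict[str, mta.GenomeMapping | None]
    p_matrix: pd.DataFrame  # mapped ASVs x phenotypes


def assign_asvs(
    hit_table: pd.DataFrame,
    collection: ReferenceCollection,
    bpm: BinaryPhenotypeMatrix,
    params: mta.HitSelectionParams = mta.HitSelectionParams(),
) -> AssignmentSet:
    """Top-hit selection, MTA, genome mapping, and carrier probabilities."""
    grouped = mta.hits_by_query(hit_table)
    mtas: dict[str, mta.MultiTaxonomicAssignment] = {}
    mappings: dict[str, mta.GenomeMapping | None] = {}
    for asv, hits in grouped.items():
        selected = mta.select_top_hits(hits, params)
        if selected:
            mtas[asv] = mta.build_mta(selected, collection.lineage_of_sequence)
        mappings[asv] = mta.map_asv_to_genomes(
            hits, sequence_genome_id, params
        )
    p_matrix = profiles.probability_matrix(mappings, bpm)
    return AssignmentSet(mtas=mtas, mappings=mappings, p_matrix=p_matrix)


def build_study(
    datasets: Sequence[profiles.ASVDataset],
    assignments: AssignmentSet,
    min_reads: int = DEFAULT_MIN_READS,
    carrier_threshold: float = profiles.CARRIER_THRESHOLD,
) -> ml.StudyData:
    """Filter cohorts and assemble taxonomy + phenotype feature tables.

    Per cohort: coverage filter (> ``min_reads``), ASV retention filter
    with renormalization, genus-level MTA aggregation, CPI, and PAD on a
    neighbor-joining tree over the cohort's retained rep seqs.
    """
    features: dict[str, dict[str, pd.DataFrame]] = {"taxonomy": {}, "phenotype": {}}
    labels: dict[str, pd.Series] = {}
    pad: dict[str, pd.DataFrame] = {}
    for ds in datasets:
        ds = profiles.filter_by_coverage(ds, min_reads)
        ds = profiles.filter_asv_table(ds)
        features["taxonomy"][ds.dataset_id] = mta.aggregate_genus_features(
            ds.abundance, assignments.mtas
        )
        features["phenotype"][ds.dataset_id] = profiles.compute_cpi(
            ds, assignments.p_matrix
        )
        tree = trees.build_tree(ds.rep_seqs)
        pad[ds.dataset_id] = profiles.compute_pad(
            ds, assignments.p_matrix, tree, carrier_threshold
        )
        labels[ds.dataset_id] = ds.labels
    return ml.StudyData(features=features, labels=labels, pad=pad)


def load_study(
    data_dir, min_reads: int = DEFAULT_MIN_READS
) -> tuple[ml.StudyData, AssignmentSet]:
    """Rebuild a StudyData from the on-disk layout written by the
    simulation step (reference FASTA/TSVs, per-cohort tables, hits.tsv)."""
    from pathlib import Path

    from .reference import load_reference_collection

    data_dir = Path(data_dir)
    collection, bpm = load_reference_collection(
        data_dir / "reference_16s.fasta",
        data_dir / "reference_lineages.tsv",
        data_dir / "bpm.tsv",
        data_dir / "bpm_categories.tsv",
    )
    hits = mta.load_hit_table(data_dir / "hits.tsv")
    labels = pd.read_csv(data_dir / "labels.tsv", sep="\t")
    datasets = [
        profiles.read_asv_dataset(
            ds_id,
            data_dir / f"{ds_id}_abundance.tsv",
            data_dir / f"{ds_id}_rep_seqs.fasta",
            data_dir / "labels.tsv",
        )
        for ds_id in sorted(labels["dataset_id"].unique())
    ]
    assignments = assign_asvs(hits, collection, bpm)
    return build_study(datasets, assignments, min_reads=min_reads), assignments


def simulate_study(
    scenario: simulate.SyntheticScenario,
    min_reads: int = DEFAULT_MIN_READS,
) -> tuple[ml.StudyData, simulate.ReferenceBundle, simulate.GroundTruth]:
    """Generate a synthetic study and push it through the profiling stages."""
    bundle, truth = simulate.generate_reference(scenario)
    datasets = simulate.generate_datasets(scenario, bundle, truth)
    asv_seqs = simulate.asv_sequences(scenario, bundle, truth)
    hits = simulate.generate_hits(asv_seqs, bundle.collection.all_sequences())
    assignments = assign_asvs(hits, bundle.collection, bundle.bpm)
    study = build_study(datasets, assignments, min_reads=min_reads)
    return study, bundle, truth


def run_variant_suite(
    study: ml.StudyData,
    predictor_set: str,
    contrast: str,
    master_seed: int = 0,
) -> tuple[dict[str, pd.Series], dict[str, dict[str, float]]]:
    """All 7 strategy-variant classifiers for one predictor set x contrast.

    Returns variant-level importances (zeroed for features missed in any
    iteration) and per-variant metric summaries.
    """
    configs = [
        c
        for c in ml.enumerate_configs(study.dataset_ids)
        if c.predictor_set == predictor_set and c.contrast == contrast
    ]
    importances: dict[str, pd.Series] = {}
    summaries: dict[str, dict[str, float]] = {}
    for config in configs:
        results = ml.train_and_evaluate(config, study, master_seed)
        importances[config.variant_key] = ml.variant_importances(results)
        summaries[config.variant_key] = ml.summarize(results)
    return importances, summaries


def stable_predictors(
    study: ml.StudyData,
    predictor_set: str,
    contrast: str,
    master_seed: int = 0,
) -> tuple[list[biomarkers.StablePredictorReport], dict[str, dict[str, float]]]:
    """Run the variant suite and apply both stability criteria."""
    importances, summaries = run_variant_suite(
        study, predictor_set, contrast, master_seed
    )
    diffs = biomarkers.group_mean_differences(
        study.features[predictor_set], study.labels, contrast
    )
    # "all but one variant" — six of the seven for a three-cohort study,
    # scaled down for studies with fewer cohorts
    min_variants = max(1, len(importances) - 1)
    reports = biomarkers.identify_stable_predictors(
        importances, diffs, predictor_set, contrast,
        min_variants=min_variants,
    )
    return reports, summaries


def stable_predictor_pdps(
    study: ml.StudyData,
    stable_features: Sequence[str],
    predictor_set: str,
    contrast: str,
    master_seed: int = 0,
    n_iterations: int = 20,
    rf: ml.RFParams = ml.RFParams(),
) -> dict[str, tuple[biomarkers.PDPCurve, str]]:
    """Mean PDP and form label per stable predictor.

    Mixed-strategy classifiers are refit on the stable predictors alone
    over ``n_iterations`` iterations; per-iteration curves share a common
    grid spanning the union of training ranges and are averaged pointwise
    before form classification.
    """
    if not stable_features:
        return {}
    config = ml.ClassifierConfig(
        strategy="Mixed",
        strategy_variant="all",
        predictor_set=predictor_set,
        contrast=contrast,
        rf=rf,
        n_iterations=n_iterations,
    )
    tables = study.features[predictor_set]
    columns = pd.Index(stable_features)
    fits: list[tuple[object, pd.DataFrame]] = []
    for it in range(n_iterations):
        train_ids, _ = ml._plan_iteration(config, study, it, master_seed)
        X_train = ml._assemble(tables, train_ids, columns)
        y_all = pd.concat([study.labels[d] for d in study.dataset_ids])
        y_train = (y_all.loc[X_train.index] == contrast).astype(int)
        model = rf.make(ml.derive_seed(master_seed, "pdp", config.variant_key,
                                       contrast, predictor_set, it))
        model.fit(X_train.to_numpy(), y_train.to_numpy())
        fits.append((model, X_train))

    out: dict[str, tuple[biomarkers.PDPCurve, str]] = {}
    for feature in stable_features:
        lo = min(float(X[feature].min()) for _, X in fits)
        hi = max(float(X[feature].max()) for _, X in fits)
        curves = [
            biomarkers.compute_pdp(model, X, feature, grid_range=(lo, hi))
            for model, X in fits
        ]
        mean_curve = biomarkers.average_curves(curves)
        out[feature] = (mean_curve, biomarkers.classify_pdp_form(mean_curve))
    return out
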