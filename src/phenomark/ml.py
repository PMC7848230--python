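"""Cross-study random-forest classification of clinical status.

Classifier configurations cross three dataset-division strategies with two
predictor sets (genus-level taxonomy abundances vs phenotype CPI profiles)
and two case/control contrasts (CD vs HC, UC vs HC):

* Single — one cohort, stratified two-thirds / one-third train/test split;
* Mixed — all cohorts pooled after per-status subsampling to the smallest
  cohort's group size (redrawn each iteration), then a 2/3 split;
* L1O — leave-one-dataset-out: train on the other cohorts (subsampled to
  equal per-status counts), test on the entire held-out cohort.

With three cohorts this yields 7 division variants (3 Single + 3 L1O + 1
Mixed) and 28 configurations overall. Every iteration re-runs feature
filtration (training data only, per dataset for multi-cohort strategies)
and feature extraction (10 sub-iteration forests, top 20 by mean Gini
importance) before the final fit with the fixed hyperparameters: depth 3,
200 trees, 50% of features per split, balanced class weights.

Randomness is funnelled through one master seed: per-iteration and
per-sub-iteration seeds derive deterministically from (master seed,
strategy, variant, iteration), so any single iteration can be re-run in
isolation and the whole pipeline is bit-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

PREDICTOR_SETS = ("taxonomy", "phenotype")
CONTRASTS = ("CD", "UC")


@dataclass(frozen=True)
class RFParams:
    """The fixed random-forest hyperparameters."""

    max_depth: int = 3
    n_estimators: int = 200
    max_features: float = 0.5  # fraction of features tried at each split
    class_weight: str = "balanced"

    def make(self, seed: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            max_depth=self.max_depth,
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            class_weight=self.class_weight,
            random_state=seed,
        )


@dataclass(frozen=True)
class ClassifierConfig:
    strategy: str  # "Single" | "Mixed" | "L1O"
    strategy_variant: str  # dataset id, or "all" for Mixed
    predictor_set: str  # "taxonomy" | "phenotype"
    contrast: str  # "CD" | "UC"
    rf: RFParams = RFParams()
    n_iterations: int = 10
    n_subiterations: int = 10
    top_k: int = 20

    @property
    def variant_key(self) -> str:
        return f"{self.strategy}:{self.strategy_variant}"


@dataclass
class IterationResult:
    auc: float
    sensitivity: float
    specificity: float
    feature_importances: pd.Series  # extracted features -> Gini importance
    features: list[str]


def derive_seed(master_seed: int, *tokens) -> int:
    """Deterministic child seed (< 2**31) from a master seed and tokens."""
    ints = [int(master_seed)] + [
        zlib.crc32(str(t).encode()) for t in tokens
    ]
    return int(np.random.SeedSequence(ints).generate_state(1)[0] >> 1)


def enumerate_configs(
    dataset_ids: Sequence[str],
    predictor_sets: Sequence[str] = PREDICTOR_SETS,
    contrasts: Sequence[str] = CONTRASTS,
    rf: RFParams = RFParams(),
) -> list[ClassifierConfig]:
    """All strategy-variant x predictor-set x contrast configurations.

    Variants: one Single per dataset, one L1O per held-out dataset (only
    defined for >= 2 datasets), and one Mixed over all datasets (ditto).
    Three datasets give 7 variants and 28 configurations.
    """
    datasets = list(dataset_ids)
    variants: list[tuple[str, str, int]] = [
        ("Single", d, 10) for d in datasets
    ]
    if len(datasets) >= 2:
        variants += [("L1O", d, 3) for d in datasets]
        variants += [("Mixed", "all", 10)]
    return [
        ClassifierConfig(
            strategy=s,
            strategy_variant=v,
            predictor_set=ps,
            contrast=c,
            rf=rf,
            n_iterations=n_it,
        )
        for ps in predictor_sets
        for c in contrasts
        for s, v, n_it in variants
    ]


def equalized_counts(
    counts_by_dataset: Mapping[str, Mapping[str, int]]
) -> dict[str, int]:
    """Per-status subsample target: the minimum count across datasets."""
    statuses = sorted({s for c in counts_by_dataset.values() for s in c})
    return {
        s: min(c.get(s, 0) for c in counts_by_dataset.values()) for s in statuses
    }


def subsample_equalize(
    ids_by_dataset: Mapping[str, Mapping[str, Sequence[str]]],
    rng: np.random.Generator,
) -> dict[str, dict[str, list[str]]]:
    """Uniform without-replacement subsample equalizing dataset contributions.

    For each status group the target size is the minimum group size across
    the participating datasets; each dataset contributes exactly that many
    samples, drawn uniformly without replacement.
    """
    targets = equalized_counts(
        {d: {s: len(ids) for s, ids in groups.items()}
         for d, groups in ids_by_dataset.items()}
    )
    out: dict[str, dict[str, list[str]]] = {}
    for d, groups in ids_by_dataset.items():
        out[d] = {}
        for s, ids in groups.items():
            chosen = rng.choice(np.asarray(ids, dtype=object),
                                size=targets[s], replace=False)
            out[d][s] = list(chosen)
    return out


def filter_taxonomic_features(
    train_tables: Sequence[pd.DataFrame],
    min_nonzero_samples: int = 5,
    min_max_abundance: float = 0.01,
) -> list[str]:
    """Taxonomic feature filtration on training data.

    A feature is dropped when, in any participating dataset's training
    part, it has nonzero abundance in fewer than 5 samples or its maximum
    abundance stays below 1%.
    """
    retained = None
    for table in train_tables:
        ok = ((table > 0).sum(axis=0) >= min_nonzero_samples) & (
            table.max(axis=0) >= min_max_abundance
        )
        names = set(table.columns[ok])
        retained = names if retained is None else retained & names
    return sorted(retained or set())


def filter_phenotype_features(
    train_cpi: Sequence[pd.DataFrame],
    train_pad: Sequence[pd.DataFrame],
    cpi_mean_range: tuple[float, float] = (0.1, 0.9),
    cpi_presence_value: float = 0.05,
    min_present_samples: int = 5,
    min_mean_pad: float = 3.5,
) -> list[str]:
    """Phenotype feature filtration on training data.

    A phenotype is dropped when, in any participating dataset's training
    part, its mean CPI falls outside [0.1, 0.9], its CPI exceeds 0.05 in
    fewer than 5 samples, or its mean PAD is below 3.5 (the phylogenetic-
    narrowness guard).
    """
    retained = None
    for cpi, pad in zip(train_cpi, train_pad):
        mean_cpi = cpi.mean(axis=0)
        ok = (
            (mean_cpi >= cpi_mean_range[0])
            & (mean_cpi <= cpi_mean_range[1])
            & ((cpi > cpi_presence_value).sum(axis=0) >= min_present_samples)
            & (pad.mean(axis=0) >= min_mean_pad)
        )
        names = set(cpi.columns[ok])
        retained = names if retained is None else retained & names
    return sorted(retained or set())


def extract_top_features(
    X: pd.DataFrame,
    y: pd.Series,
    rf: RFParams = RFParams(),
    n_subiterations: int = 10,
    top_k: int = 20,
    seed: int = 0,
) -> list[str]:
    """Top-k features by mean Gini importance over seeded sub-iterations.

    Each sub-iteration fits a forest on the full training data; per-forest
    importances (mean impurity decrease, normalized to sum 1) are averaged
    and ties break lexicographically by feature name. The selection is
    returned sorted by name (it is a set; the ranking only decides
    membership). When no more than ``top_k`` features are in play the
    ranking cannot drop any of them, so the sub-iteration fits are skipped.
    """
    if X.shape[1] == 0:
        return []
    if X.shape[1] <= top_k:
        return sorted(X.columns)
    total = np.zeros(X.shape[1])
    for k in range(n_subiterations):
        model = rf.make(derive_seed(seed, "sub", k))
        model.fit(X.to_numpy(), y.to_numpy())
        total += model.feature_importances_
    mean_imp = total / n_subiterations
    order = sorted(zip(X.columns, mean_imp), key=lambda t: (-t[1], t[0]))
    return sorted(name for name, _ in order[:top_k])


@dataclass
class StudyData:
    """Feature tables and labels for every cohort in a study.

    ``features[predictor_set][dataset_id]`` is samples x features;
    ``pad[dataset_id]`` accompanies the phenotype CPI tables for
    filtration; ``labels[dataset_id]`` maps sample -> HC/CD/UC.
    """

    features: dict[str, dict[str, pd.DataFrame]]
    labels: dict[str, pd.Series]
    pad: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def dataset_ids(self) -> list[str]:
        return sorted(self.labels)

    def contrast_ids(self, contrast: str) -> dict[str, dict[str, list[str]]]:
        """Per dataset, per status (HC + contrast), the sample ids."""
        out: dict[str, dict[str, list[str]]] = {}
        for d, lab in self.labels.items():
            out[d] = {
                s: list(lab.index[lab == s]) for s in ("HC", contrast)
            }
        return out


def _stratified_split(
    ids: list[str], y: pd.Series, train_frac: float, seed: int
) -> tuple[list[str], list[str]]:
    train, test = train_test_split(
        ids,
        train_size=train_frac,
        stratify=y.loc[ids],
        random_state=seed,
    )
    return list(train), list(test)


def _plan_iteration(
    config: ClassifierConfig,
    study: StudyData,
    it: int,
    master_seed: int,
) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Train/test sample ids per dataset for one iteration."""
    seed = derive_seed(master_seed, config.variant_key, config.contrast,
                       config.predictor_set, "iter", it)
    rng = np.random.default_rng(seed)
    ids = study.contrast_ids(config.contrast)

    if config.strategy == "Single":
        d = config.strategy_variant
        pool = ids[d]["HC"] + ids[d][config.contrast]
        y = study.labels[d]
        train, test = _stratified_split(pool, y, 2 / 3, seed)
        return {d: train}, {d: test}

    if config.strategy == "Mixed":
        chosen = subsample_equalize(ids, rng)
        train_ids: dict[str, list[str]] = {}
        test_ids: dict[str, list[str]] = {}
        for d, groups in chosen.items():
            pool = [i for g in groups.values() for i in g]
            train, test = _stratified_split(
                pool, study.labels[d], 2 / 3, derive_seed(seed, "split", d)
            )
            train_ids[d] = train
            test_ids[d] = test
        return train_ids, test_ids

    if config.strategy == "L1O":
        held_out = config.strategy_variant
        train_pool = {d: g for d, g in ids.items() if d != held_out}
        chosen = subsample_equalize(train_pool, rng)
        train_ids = {d: [i for g in groups.values() for i in g]
                     for d, groups in chosen.items()}
        test_ids = {held_out: ids[held_out]["HC"] + ids[held_out][config.contrast]}
        return train_ids, test_ids

    raise ValueError(f"unknown strategy {config.strategy!r}")


def _assemble(
    tables: Mapping[str, pd.DataFrame],
    ids_per_dataset: Mapping[str, list[str]],
    columns: pd.Index,
) -> pd.DataFrame:
    parts = [
        tables[d].reindex(columns=columns, fill_value=0.0).loc[ids]
        for d, ids in ids_per_dataset.items()
        if ids
    ]
    return pd.concat(parts, axis=0)


def run_iteration(
    config: ClassifierConfig,
    study: StudyData,
    it: int,
    master_seed: int,
) -> IterationResult:
    """One cross-validation iteration: split, filter, extract, fit, score."""
    train_ids, test_ids = _plan_iteration(config, study, it, master_seed)
    tables = study.features[config.predictor_set]
    participating = sorted(set(train_ids) | set(test_ids))
    columns = pd.Index(
        sorted(set().union(*(tables[d].columns for d in participating)))
    )

    # filtration: conditions must hold per training dataset separately
    if config.predictor_set == "phenotype":
        retained = filter_phenotype_features(
            [tables[d].loc[ids] for d, ids in train_ids.items()],
            [study.pad[d].loc[ids] for d, ids in train_ids.items()],
        )
    else:
        retained = filter_taxonomic_features(
            [tables[d].reindex(columns=columns, fill_value=0.0).loc[ids]
             for d, ids in train_ids.items()]
        )
    if not retained:
        raise ValueError(
            f"{config.variant_key}/{config.contrast}: feature filtration "
            "removed every feature"
        )

    X_train = _assemble(tables, train_ids, columns)[retained]
    X_test = _assemble(tables, test_ids, columns)[retained]
    y_all = pd.concat([study.labels[d] for d in study.dataset_ids])
    y_train = (y_all.loc[X_train.index] == config.contrast).astype(int)
    y_test = (y_all.loc[X_test.index] == config.contrast).astype(int)
    if y_train.nunique() < 2:
        raise ValueError(
            f"{config.variant_key}/{config.contrast}: a class is absent from "
            "the training fold — broken split plan"
        )

    seed = derive_seed(master_seed, config.variant_key, config.contrast,
                       config.predictor_set, "fit", it)
    final_features = extract_top_features(
        X_train, y_train, config.rf, config.n_subiterations, config.top_k, seed
    )
    model = config.rf.make(derive_seed(seed, "final"))
    model.fit(X_train[final_features].to_numpy(), y_train.to_numpy())

    disease_col = list(model.classes_).index(1)
    proba = model.predict_proba(X_test[final_features].to_numpy())[:, disease_col]
    auc = float(roc_auc_score(y_test, proba))
    pred = proba >= 0.5
    sens = float(pred[y_test.to_numpy() == 1].mean())
    spec = float((~pred[y_test.to_numpy() == 0]).mean())
    importances = pd.Series(model.feature_importances_, index=final_features)
    return IterationResult(auc, sens, spec, importances, final_features)


def train_and_evaluate(
    config: ClassifierConfig, study: StudyData, master_seed: int = 0
) -> list[IterationResult]:
    """All cross-validation iterations of one classifier configuration."""
    return [
        run_iteration(config, study, it, master_seed)
        for it in range(config.n_iterations)
    ]


def mean_importances(
    results: Sequence[IterationResult], all_features: Sequence[str]
) -> pd.Series:
    """Per-feature mean importance across iterations; non-extracted -> 0."""
    acc = pd.Series(0.0, index=pd.Index(all_features))
    for r in results:
        acc = acc.add(r.feature_importances.reindex(acc.index, fill_value=0.0))
    return acc / len(results)


def variant_importances(
    results: Sequence[IterationResult],
    all_features: Sequence[str] | None = None,
) -> pd.Series:
    """Variant-level importances feeding the stable-predictor criteria.

    A feature keeps its mean importance only when it was extracted in
    every cross-validation iteration of the variant; a feature missed in
    one or more iterations is set to zero.
    """
    union = sorted(set().union(*(r.features for r in results)))
    features = list(all_features) if all_features is not None else union
    common = set.intersection(*(set(r.features) for r in results))
    out = pd.Series(0.0, index=pd.Index(features))
    for f in common:
        if f in out.index:
            out[f] = float(np.mean([r.feature_importances[f] for r in results]))
    return out


def summarize(results: Sequence[IterationResult]) -> dict[str, float]:
    metrics = {
        "auc": [r.auc for r in results],
        "sensitivity": [r.sensitivity for r in results],
        "specificity": [r.specificity for r in results],
    }
    out: dict[str, float] = {}
    for name, vals in metrics.items():
        out[f"mean_{name}"] = float(np.mean(vals))
        out[f"sd_{name}"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return out
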