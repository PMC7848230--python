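"""Synthetic reference collections and multi-cohort case/control studies.

The generator gives every pipeline stage a self-contained test surface
shaped like the real study: several cohorts ("datasets") of healthy and
diseased subjects, phylogenetically structured ASVs that map back to a
reference genome collection, binary phenotypes that are either clustered
on the genome phylogeny (low-diversity CPI contributors the PAD filter
should remove) or spread Bernoulli-i.i.d. across it, and planted case
effects — multiplicative depletion of a taxon clade or enrichment of the
carriers of a phenotype, applied on the abundance scale before
renormalization (compositional closure shifts off-target features
slightly, as in real data).

Model sketch
------------
* Genome phylogeny: pure-birth (Yule) tree over ``n_genomes`` tips,
  rescaled to unit height; 16S-like sequences evolve along it under a
  Jukes–Cantor substitution model with ``subst_rate`` expected
  substitutions per site per unit branch length.
* Lineages: average-linkage clusters of patristic distances cut at fixed
  thresholds give phylum/family/genus labels (class and order are left
  blank, exercising missing-rank handling); species is per-genome.
* ASVs: mutated copies (0..``asv_max_mutations`` substitutions) of a
  randomly chosen source genome's 16S sequence, shared across cohorts.
* Abundances: per-ASV log-normal baselines, per-cohort batch offsets (so
  cohorts separate in ordination), per-sample noise; case samples apply
  the planted multiplicative effects; read counts are drawn log-normally
  around ``depth_mean`` and per-sample ASV counts multinomially, so rare
  ASVs drop out of individual samples as they do in real tables.

All randomness flows from ``SyntheticScenario.seed``.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .reference import (
    CATEGORIES,
    BinaryPhenotypeMatrix,
    ReferenceCollection,
    ReferenceGenome,
)
from .profiles import ASVDataset
from .mta import naive_identity

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedEffect:
    """A case-group effect: deplete a taxon clade or enrich phenotype carriers.

    ``target_kind`` is "phenotype" (target_id is a phenotype id; affected
    ASVs are those whose source genome carries it) or "genus" (target_id
    is a genus label; affected ASVs descend from that clade).
    ``log2_fc`` is the log2 fold change applied multiplicatively to the
    affected ASVs' abundances in case samples of the listed statuses.
    """

    target_kind: str  # "phenotype" | "genus"
    target_id: str
    direction: str  # "enrich" | "deplete"
    log2_fc: float = 2.0
    statuses: tuple[str, ...] = ("CD", "UC")

    @property
    def multiplier(self) -> float:
        fc = 2.0 ** self.log2_fc
        return fc if self.direction == "enrich" else 1.0 / fc


@dataclass
class SyntheticScenario:
    """Study conditions for one synthetic multi-cohort experiment."""

    n_genomes: int = 150
    n_phenotypes: int = 60
    clustered_fraction: float = 0.25  # phenotypes tied to a clade
    bernoulli_p: float = 0.5  # carrier probability of diffuse phenotypes
    clade_size_range: tuple[float, float] = (0.1, 0.5)
    birth_rate: float = 1.0
    seq_length: int = 250  # 16S V4-like amplicon length
    subst_rate: float = 0.35  # substitutions/site per unit branch length
    n_asvs: int = 300
    asv_max_mutations: int = 3
    n_datasets: int = 3
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"HC": 60, "CD": 30, "UC": 30}
    )
    base_sigma: float = 1.0  # per-ASV log-normal baseline spread
    batch_sigma: float = 0.75  # cohort batch offsets (log scale)
    noise_sigma: float = 1.0  # per-sample log-normal noise
    depth_mean: float = 30000.0
    depth_sigma: float = 0.2  # log-normal sd of read depth
    planted_effects: tuple[PlantedEffect, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 1")
        for e in self.planted_effects:
            if not np.isfinite(e.log2_fc):
                raise ValueError("effect sizes must be finite")

    def rng(self, *tokens) -> np.random.Generator:
        import zlib

        ints = [self.seed] + [zlib.crc32(str(t).encode()) for t in tokens]
        return np.random.default_rng(np.random.SeedSequence(ints))


def scenario_from_yaml(path: str | Path) -> SyntheticScenario:
    """Load a scenario from a YAML mapping of field names to values."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    effects = tuple(
        PlantedEffect(
            target_kind=e["target_kind"],
            target_id=e["target_id"],
            direction=e["direction"],
            log2_fc=float(e.get("log2_fc", 2.0)),
            statuses=tuple(e.get("statuses", ("CD", "UC"))),
        )
        for e in raw.pop("planted_effects", [])
    )
    if "clade_size_range" in raw:
        raw["clade_size_range"] = tuple(raw["clade_size_range"])
    scenario = SyntheticScenario(planted_effects=effects, **raw)
    scenario.validate()
    return scenario


def scenario_to_yaml(scenario: SyntheticScenario, path: str | Path) -> None:
    import yaml

    raw = asdict(scenario)
    raw["planted_effects"] = [asdict(e) for e in scenario.planted_effects]
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class ReferenceBundle:
    collection: ReferenceCollection
    bpm: BinaryPhenotypeMatrix
    tree: dendropy.Tree  # true genome phylogeny, unit height

    @property
    def newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()


@dataclass
class GroundTruth:
    asv_source: dict[str, str]  # asv_id -> source genome id
    planted_effects: tuple[PlantedEffect, ...]
    true_tree_newick: str

    def affected_asvs(self, effect: PlantedEffect, bundle: ReferenceBundle) -> list[str]:
        out = []
        for asv, gid in self.asv_source.items():
            genome = bundle.collection[gid]
            if effect.target_kind == "phenotype":
                if bundle.bpm.values.at[gid, effect.target_id] == 1:
                    out.append(asv)
            elif effect.target_kind == "genus":
                if genome.lineage[5] == effect.target_id:
                    out.append(asv)
            else:
                raise ValueError(f"unknown target kind {effect.target_kind!r}")
        return out


def _evolve_sequences(
    tree: dendropy.Tree, seq_length: int, subst_rate: float, rng: np.random.Generator
) -> dict[str, str]:
    """Jukes–Cantor-style sequence evolution along the tree."""
    root_seq = rng.integers(0, 4, size=seq_length)
    seqs: dict[str, str] = {}
    stack = [(tree.seed_node, root_seq)]
    while stack:
        node, seq = stack.pop()
        for child in node.child_nodes():
            t = (child.edge.length or 0.0) * subst_rate
            p_sub = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
            child_seq = seq.copy()
            hit = rng.random(seq_length) < p_sub
            if hit.any():
                # substitute to one of the three other bases
                child_seq[hit] = (
                    child_seq[hit] + rng.integers(1, 4, size=int(hit.sum()))
                ) % 4
            if child.is_leaf():
                seqs[child.taxon.label] = "".join(_BASES[child_seq])
            else:
                stack.append((child, child_seq))
    return seqs


def _lineages_from_tree(
    tree: dendropy.Tree, rng: np.random.Generator
) -> dict[str, tuple[str, ...]]:
    """Nested phylum/family/genus labels from patristic-distance clustering."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    link = average(squareform(d, checks=False))
    cuts = {"phylum": 1.5, "family": 0.9, "genus": 0.45}
    labels = {
        rank: fcluster(link, t=t, criterion="distance")
        for rank, t in cuts.items()
    }
    lineages = {}
    for i, taxon in enumerate(taxa):
        gid = taxon.label
        lineages[gid] = (
            "Bacteria",
            f"Phy{labels['phylum'][i]:02d}",
            "",
            "",
            f"Fam{labels['family'][i]:03d}",
            f"Gen{labels['genus'][i]:03d}",
            f"sp_{gid}",
        )
    return lineages


def _clade_tip_sets(tree: dendropy.Tree) -> list[list[str]]:
    out = []
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        out.append([t.taxon.label for t in node.leaf_iter()])
    return out


def generate_reference(scenario: SyntheticScenario) -> tuple[ReferenceBundle, GroundTruth]:
    """Genome phylogeny, 16S sequences, lineages, BPM, and the ASV pool.

    Clustered phenotypes put carriers on a connected clade of the true
    tree (strong phylogenetic signal, low diversity); diffuse phenotypes
    assign carriers Bernoulli-i.i.d. (high diversity). The ASV pool —
    mutated copies of reference 16S genes — is drawn here too, since it
    is shared by every cohort; its source-genome map goes into the
    returned ground truth.
    """
    scenario.validate()
    rng = scenario.rng("reference")
    tree = treesim.birth_death_tree(
        birth_rate=scenario.birth_rate,
        death_rate=0.0,
        num_extant_tips=scenario.n_genomes,
        rng=random.Random(int(rng.integers(2**31))),
    )
    for i, taxon in enumerate(tree.taxon_namespace):
        taxon.label = f"g{i + 1:04d}"
    height = max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= height

    seqs = _evolve_sequences(tree, scenario.seq_length, scenario.subst_rate, rng)
    lineages = _lineages_from_tree(tree, rng)
    genomes = {
        gid: ReferenceGenome(gid, lineages[gid], {f"{gid}__r1": seqs[gid]})
        for gid in sorted(seqs)
    }
    collection = ReferenceCollection(genomes)
    gids = sorted(genomes)

    n_clustered = int(round(scenario.clustered_fraction * scenario.n_phenotypes))
    lo, hi = scenario.clade_size_range
    clades = [
        c
        for c in _clade_tip_sets(tree)
        if lo * scenario.n_genomes <= len(c) <= hi * scenario.n_genomes
    ]
    values = {}
    categories = {}
    for k in range(n_clustered):
        name = f"phen_clade_{k + 1:02d}"
        clade = clades[int(rng.integers(len(clades)))] if clades else gids[: len(gids) // 3]
        col = pd.Series(0, index=gids)
        col.loc[sorted(clade)] = 1
        values[name] = col
        categories[name] = CATEGORIES[k % len(CATEGORIES)]
    for k in range(scenario.n_phenotypes - n_clustered):
        name = f"phen_rand_{k + 1:02d}"
        values[name] = pd.Series(
            (rng.random(len(gids)) < scenario.bernoulli_p).astype(int), index=gids
        )
        categories[name] = CATEGORIES[k % len(CATEGORIES)]
    bpm = BinaryPhenotypeMatrix(
        values=pd.DataFrame(values), categories=pd.Series(categories)
    )
    bpm.validate()

    # shared ASV pool: mutated copies of reference 16S sequences
    arng = scenario.rng("asvs")
    asv_source: dict[str, str] = {}
    for k in range(scenario.n_asvs):
        asv_source[f"asv_{k + 1:04d}"] = gids[int(arng.integers(len(gids)))]

    truth = GroundTruth(
        asv_source=asv_source,
        planted_effects=scenario.planted_effects,
        true_tree_newick=tree.as_string(schema="newick").strip(),
    )
    return ReferenceBundle(collection, bpm, tree), truth


def asv_sequences(
    scenario: SyntheticScenario, bundle: ReferenceBundle, truth: GroundTruth
) -> dict[str, str]:
    """Mutate each ASV's source 16S sequence by 0..max substitutions."""
    rng = scenario.rng("asv_seqs")
    out: dict[str, str] = {}
    for asv, gid in truth.asv_source.items():
        seq = list(next(iter(bundle.collection[gid].sixteen_s.values())))
        n_mut = int(rng.integers(0, scenario.asv_max_mutations + 1))
        for pos in rng.choice(len(seq), size=n_mut, replace=False):
            current = seq[pos]
            options = [b for b in "ACGT" if b != current]
            seq[pos] = options[int(rng.integers(3))]
        out[asv] = "".join(seq)
    return out


def generate_datasets(
    scenario: SyntheticScenario, bundle: ReferenceBundle, truth: GroundTruth
) -> list[ASVDataset]:
    """Multi-cohort abundance tables with planted case effects.

    Returns one ASVDataset per cohort, sharing the ASV pool's rep seqs.
    """
    rep_seqs = asv_sequences(scenario, bundle, truth)
    asvs = list(rep_seqs)
    n_asv = len(asvs)
    rng = scenario.rng("datasets")
    base_mu = rng.normal(0.0, scenario.base_sigma, size=n_asv)

    multipliers_by_status: dict[str, np.ndarray] = {}
    for status in ("CD", "UC"):
        mult = np.ones(n_asv)
        for eff in scenario.planted_effects:
            if status not in eff.statuses:
                continue
            hit = truth.affected_asvs(eff, bundle)
            idx = [asvs.index(a) for a in hit]
            mult[idx] *= eff.multiplier
        multipliers_by_status[status] = mult

    datasets = []
    for d in range(scenario.n_datasets):
        ds_id = f"D{d + 1}"
        batch = rng.normal(0.0, scenario.batch_sigma, size=n_asv)
        rows, sample_ids, statuses, depths = [], [], [], []
        for status, size in scenario.group_sizes.items():
            for k in range(size):
                noise = rng.normal(0.0, scenario.noise_sigma, size=n_asv)
                x = np.exp(base_mu + batch + noise)
                if status in multipliers_by_status:
                    x = x * multipliers_by_status[status]
                p = x / x.sum()
                depth = int(
                    np.exp(rng.normal(np.log(scenario.depth_mean), scenario.depth_sigma))
                )
                counts = rng.multinomial(depth, p)
                rows.append(counts / depth)
                sample_ids.append(f"{ds_id}_{status}_{k + 1:03d}")
                statuses.append(status)
                depths.append(depth)
        ds = ASVDataset(
            dataset_id=ds_id,
            abundance=pd.DataFrame(rows, index=sample_ids, columns=asvs),
            read_counts=pd.Series(depths, index=sample_ids),
            rep_seqs=dict(rep_seqs),
            labels=pd.Series(statuses, index=sample_ids),
        )
        ds.validate()
        datasets.append(ds)
    return datasets


def generate_hits(
    asv_seqs: dict[str, str],
    reference_seqs: dict[str, str],
    min_report: float = 0.75,
) -> pd.DataFrame:
    """All-vs-all alignment-hit table (query_id, subject_id, identity).

    Identities come from :func:`phenomark.mta.naive_identity`; pairs below
    ``min_report`` are omitted (they could never pass the drop threshold).
    """
    records = []
    for asv, qseq in asv_seqs.items():
        for sid, sseq in reference_seqs.items():
            f = naive_identity(qseq, sseq)
            if f >= min_report:
                records.append((asv, sid, f))
    return pd.DataFrame(records, columns=["query_id", "subject_id", "identity"])


def write_scenario_data(
    scenario: SyntheticScenario,
    bundle: ReferenceBundle,
    truth: GroundTruth,
    datasets: Sequence[ASVDataset],
    out_dir: str | Path,
) -> None:
    """Write FASTA/TSV/labels in the formats the pipeline consumes."""
    from .profiles import write_asv_dataset

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.collection.write_fasta(out / "reference_16s.fasta")
    bundle.collection.write_lineages(out / "reference_lineages.tsv")
    bundle.bpm.to_tsv(out / "bpm.tsv", out / "bpm_categories.tsv")
    labels = []
    for ds in datasets:
        write_asv_dataset(ds, out)
        for s in ds.sample_ids:
            labels.append((s, ds.dataset_id, ds.labels.loc[s]))
    pd.DataFrame(labels, columns=["sample_id", "dataset_id", "status"]).to_csv(
        out / "labels.tsv", sep="\t", index=False
    )
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "asv_source": truth.asv_source,
                "planted_effects": [asdict(e) for e in truth.planted_effects],
                "true_tree_newick": truth.true_tree_newick,
                "seed": scenario.seed,
            },
            fh,
            indent=2,
        )
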