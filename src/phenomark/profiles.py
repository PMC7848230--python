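"""ASV datasets, filtering rules, and CPI / PAD phenotype profiles.

The Community Phenotype Index of a sample for a binary phenotype is

    CPI = sum_i p_i * A_i

over ASVs i, where A_i is the ASV's relative abundance and p_i the
probability that its cells carry the phenotype — the mapping-weighted
average of the 0/1 BPM column over the reference genomes the ASV maps to.
CPI is the expected fraction of cells in the community possessing the
phenotype. Unassigned ASVs (no genome mapping) have undefined p_i and
contribute 0, but their abundance stays in the denominator: unknown cells
dilute the index rather than inflate it.

Phenotype Alpha Diversity (PAD) is Faith's phylogenetic diversity of the
sub-community of carrier ASVs — those present in the sample (abundance
> 0) whose carrier probability p_i exceeds 0.6 (strict). PAD = 0 when no
carrier is present. Low PAD flags phenotypes whose CPI merely tracks one
narrow clade, which the classifier feature filter later removes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from skbio import TreeNode

from .reference import BinaryPhenotypeMatrix
from .mta import GenomeMapping
from .trees import FaithCalculator

STATUSES = ("HC", "CD", "UC")

#: default carrier-probability cutoff for PAD (strict >)
CARRIER_THRESHOLD = 0.6


@dataclass
class ASVDataset:
    """One cohort: abundances, read counts, rep seqs, clinical labels."""

    dataset_id: str
    abundance: pd.DataFrame  # samples x ASVs, relative abundances
    read_counts: pd.Series  # sample -> total reads
    rep_seqs: dict[str, str]  # asv_id -> sequence
    labels: pd.Series  # sample -> status in STATUSES

    def validate(self) -> None:
        sums = self.abundance.sum(axis=1)
        off = sums[(sums - 1.0).abs() > 1e-9]
        if len(off):
            raise ValueError(
                f"{self.dataset_id}: per-sample abundances do not sum to 1 for "
                f"samples {list(off.index[:5])}"
            )
        if (self.read_counts < 0).any():
            raise ValueError(f"{self.dataset_id}: negative read counts")
        missing = [a for a in self.abundance.columns if a not in self.rep_seqs]
        if missing:
            raise ValueError(
                f"{self.dataset_id}: ASVs without representative sequence: "
                f"{missing[:5]}"
            )
        bad = set(self.labels.unique()) - set(STATUSES)
        if bad:
            raise ValueError(f"{self.dataset_id}: unknown statuses {sorted(bad)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.abundance.index

    @property
    def asv_ids(self) -> pd.Index:
        return self.abundance.columns


def filter_asv_table(
    dataset: ASVDataset,
    presence_frac: float = 0.005,
    mean_abund: float = 0.0025,
    max_abund: float = 0.005,
    renormalize: bool = True,
) -> ASVDataset:
    """Keep ASVs passing at least one retention criterion; renormalize.

    An ASV is retained when (i) it is present (abundance > 0) in more than
    ``presence_frac`` of samples, OR (ii) its dataset-average abundance
    exceeds ``mean_abund``, OR (iii) its maximum abundance exceeds
    ``max_abund`` (all strict). Abundances are renormalized per sample
    afterwards so CPI keeps its fraction-of-cells reading.
    """
    ab = dataset.abundance
    presence = (ab > 0).mean(axis=0) > presence_frac
    mean_ok = ab.mean(axis=0) > mean_abund
    max_ok = ab.max(axis=0) > max_abund
    keep = ab.columns[presence | mean_ok | max_ok]
    if len(keep) == 0:
        raise ValueError(f"{dataset.dataset_id}: ASV filter removed every ASV")
    filtered = ab[keep].copy()
    if renormalize:
        totals = filtered.sum(axis=1)
        filtered = filtered.div(totals.replace(0.0, np.nan), axis=0).fillna(0.0)
    return replace(
        dataset,
        abundance=filtered,
        rep_seqs={a: dataset.rep_seqs[a] for a in keep},
    )


def filter_by_coverage(dataset: ASVDataset, min_reads: int) -> ASVDataset:
    """Drop samples whose read count is not strictly above ``min_reads``."""
    keep = dataset.read_counts.index[dataset.read_counts > min_reads]
    keep = [s for s in dataset.sample_ids if s in set(keep)]
    return replace(
        dataset,
        abundance=dataset.abundance.loc[keep],
        read_counts=dataset.read_counts.loc[keep],
        labels=dataset.labels.loc[keep],
    )


def phenotype_probability(
    mapping: GenomeMapping, bpm: BinaryPhenotypeMatrix
) -> pd.Series:
    """p_i per phenotype: mapping-weighted average of the BPM rows."""
    missing = [g for g in mapping.weights if g not in bpm.genome_ids]
    if missing:
        raise KeyError(
            f"ASV {mapping.asv_id!r} maps to genomes missing from the BPM: {missing}"
        )
    weights = pd.Series(mapping.weights)
    return bpm.values.loc[weights.index].mul(weights, axis=0).sum(axis=0)


def probability_matrix(
    mappings: Mapping[str, GenomeMapping | None], bpm: BinaryPhenotypeMatrix
) -> pd.DataFrame:
    """Stack p_i rows for every mapped ASV (unmapped ASVs are absent)."""
    rows = {
        asv: phenotype_probability(m, bpm)
        for asv, m in mappings.items()
        if m is not None
    }
    if not rows:
        return pd.DataFrame(columns=bpm.phenotype_ids)
    return pd.DataFrame(rows).T


def compute_cpi(dataset: ASVDataset, p_matrix: pd.DataFrame) -> pd.DataFrame:
    """Samples x phenotypes CPI = sum_i p_i A_i; unmapped ASVs add 0."""
    mapped = [a for a in dataset.asv_ids if a in p_matrix.index]
    if not mapped:
        return pd.DataFrame(
            0.0, index=dataset.sample_ids, columns=p_matrix.columns
        )
    return dataset.abundance[mapped] @ p_matrix.loc[mapped]


def compute_pad(
    dataset: ASVDataset,
    p_matrix: pd.DataFrame,
    tree: TreeNode,
    carrier_threshold: float = CARRIER_THRESHOLD,
) -> pd.DataFrame:
    """Samples x phenotypes PAD matrix via vectorised Faith's PD.

    Per phenotype, carrier ASVs are those with p_i strictly above the
    threshold; per sample, Faith's PD is taken over the carriers present
    (abundance > 0). No carriers present gives PAD 0.
    """
    calc = FaithCalculator(tree)
    tip_pos = {t: i for i, t in enumerate(calc.tip_ids)}
    asvs = [a for a in dataset.asv_ids if a in p_matrix.index and a in tip_pos]
    present = dataset.abundance[asvs].to_numpy() > 0  # samples x asvs
    inc = calc.incidence[[tip_pos[a] for a in asvs]]  # asvs x edges
    out = np.zeros((len(dataset.sample_ids), p_matrix.shape[1]))
    p = p_matrix.loc[asvs].to_numpy()
    for k in range(p_matrix.shape[1]):
        carriers = p[:, k] > carrier_threshold
        if not carriers.any():
            continue
        member = present[:, carriers]  # samples x carriers
        covered = member.astype(np.float64) @ inc[carriers]
        out[:, k] = (covered > 0) @ calc.lengths
    return pd.DataFrame(out, index=dataset.sample_ids, columns=p_matrix.columns)


def write_profile(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="sample_id")


def read_asv_dataset(
    dataset_id: str,
    abundance_tsv: str | Path,
    rep_seqs_fasta: str | Path,
    labels_tsv: str | Path,
) -> ASVDataset:
    """Load one cohort from the pipeline's on-disk TSV/FASTA layout.

    ``abundance_tsv``: samples x ASVs with a ``sample_id`` index column and
    a ``read_count`` column; ``labels_tsv``: sample_id, dataset_id, status.
    """
    from Bio import SeqIO

    table = pd.read_csv(abundance_tsv, sep="\t", index_col="sample_id")
    table.index.name = None
    read_counts = table.pop("read_count")
    labels_all = pd.read_csv(labels_tsv, sep="\t")
    labels_all = labels_all[labels_all["dataset_id"] == dataset_id]
    labels = labels_all.set_index("sample_id")["status"].loc[table.index]
    rep_seqs = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(rep_seqs_fasta), "fasta")
    }
    ds = ASVDataset(
        dataset_id=dataset_id,
        abundance=table,
        read_counts=read_counts,
        rep_seqs={a: rep_seqs[a] for a in table.columns},
        labels=labels,
    )
    ds.validate()
    return ds


def write_asv_dataset(dataset: ASVDataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = dataset.abundance.copy()
    table.insert(0, "read_count", dataset.read_counts)
    table.to_csv(out / f"{dataset.dataset_id}_abundance.tsv", sep="\t",
                 index_label="sample_id")
    with open(out / f"{dataset.dataset_id}_rep_seqs.fasta", "w") as fh:
        for asv, seq in dataset.rep_seqs.items():
            fh.write(f">{asv}\n{seq}\n")
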