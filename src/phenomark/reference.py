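"""Reference genome collection and binary phenotype matrices.

The pipeline scores community metabolic potential against a reference
collection of microbial genomes, each carrying one or more 16S rRNA gene
sequences, a taxonomic lineage, and a row in a Binary Phenotype Matrix
(BPM): a genomes x phenotypes 0/1 table where a 1 means the genome encodes
a complete pathway for that phenotype (vitamin or amino-acid synthesis,
amino-acid degradation, sugar utilization, SCFA production) or carries at
least one enzyme of a glycosyl-hydrolase (GH) family.

File conventions
----------------
* 16S FASTA: record ids are ``<genome_id>`` or ``<genome_id>__r<k>`` when a
  genome has multiple 16S copies; :func:`sequence_genome_id` strips the
  copy suffix.
* Lineage TSV: ``genome_id`` column plus one column per rank in
  :data:`RANKS`; empty cells mark missing ranks.
* BPM TSV: ``genome_id`` rows, one column per phenotype, cells in {0,1};
  phenotype categories live in a sidecar TSV (``phenotype_id\tcategory``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: phenotype categories used in the BPM
CATEGORIES = (
    "vitamin synthesis",
    "amino-acid synthesis",
    "amino-acid degradation",
    "sugar utilization",
    "SCFA production",
    "GH family",
)

_ALPHABET = set("ACGTN")


class ValidationError(ValueError):
    """Raised with every collected violation, each naming its coordinates."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


def sequence_genome_id(seq_id: str) -> str:
    """Genome id for a 16S sequence id (strips a ``__r<k>`` copy suffix)."""
    return seq_id.split("__")[0]


@dataclass
class ReferenceGenome:
    """A reference genome: id, ordered lineage, and its 16S sequences.

    ``lineage`` is aligned with :data:`RANKS`; missing ranks are empty
    strings so rank-wise access stays positional.
    """

    genome_id: str
    lineage: tuple[str, ...]
    sixteen_s: dict[str, str] = field(default_factory=dict)  # seq_id -> sequence

    def __post_init__(self) -> None:
        if len(self.lineage) != len(RANKS):
            raise ValueError(
                f"lineage of {self.genome_id} has {len(self.lineage)} ranks, "
                f"expected {len(RANKS)}"
            )


@dataclass
class BinaryPhenotypeMatrix:
    """Genomes x phenotypes 0/1 table with a per-phenotype category."""

    values: pd.DataFrame  # genomes x phenotypes, int {0,1}
    categories: pd.Series  # phenotype_id -> category

    @property
    def genome_ids(self) -> pd.Index:
        return self.values.index

    @property
    def phenotype_ids(self) -> pd.Index:
        return self.values.columns

    def validate(self) -> None:
        problems = []
        bad = (self.values != 0) & (self.values != 1)
        for g, p in zip(*bad.values.nonzero()):
            problems.append(
                f"non-binary BPM cell at genome={self.values.index[g]!r}, "
                f"phenotype={self.values.columns[p]!r}: {self.values.iat[g, p]!r}"
            )
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            problems.append(f"duplicate genome rows: {list(dups)}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            problems.append(f"duplicate phenotype columns: {list(dups)}")
        missing_cat = self.values.columns.difference(self.categories.index)
        if len(missing_cat):
            problems.append(f"phenotypes without category: {list(missing_cat)}")
        if problems:
            raise ValidationError(problems)

    def to_tsv(self, bpm_path: str | Path, categories_path: str | Path) -> None:
        self.values.to_csv(bpm_path, sep="\t", index_label="genome_id")
        self.categories.rename("category").to_csv(
            categories_path, sep="\t", index_label="phenotype_id"
        )

    @classmethod
    def from_tsv(
        cls, bpm_path: str | Path, categories_path: str | Path | None = None
    ) -> "BinaryPhenotypeMatrix":
        values = pd.read_csv(bpm_path, sep="\t", index_col="genome_id")
        values.index.name = None
        if categories_path is not None:
            categories = pd.read_csv(
                categories_path, sep="\t", index_col="phenotype_id"
            )["category"]
        else:
            categories = pd.Series("GH family", index=values.columns)
        bpm = cls(values=values, categories=categories)
        bpm.validate()
        return bpm


@dataclass
class ReferenceCollection:
    """All reference genomes, indexed by genome id."""

    genomes: dict[str, ReferenceGenome]

    def __len__(self) -> int:
        return len(self.genomes)

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self.genomes

    def __getitem__(self, genome_id: str) -> ReferenceGenome:
        return self.genomes[genome_id]

    @property
    def genome_ids(self) -> list[str]:
        return list(self.genomes)

    def all_sequences(self) -> dict[str, str]:
        """Flat seq_id -> sequence map over every 16S copy."""
        out: dict[str, str] = {}
        for g in self.genomes.values():
            out.update(g.sixteen_s)
        return out

    def lineage_of_sequence(self, seq_id: str) -> tuple[str, ...]:
        gid = sequence_genome_id(seq_id)
        if gid not in self.genomes:
            raise KeyError(f"sequence {seq_id!r} resolves to unknown genome {gid!r}")
        return self.genomes[gid].lineage

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for g in self.genomes.values():
                for sid, seq in g.sixteen_s.items():
                    fh.write(f">{sid}\n{seq}\n")

    def write_lineages(self, path: str | Path) -> None:
        rows = {
            gid: dict(zip(RANKS, g.lineage)) for gid, g in self.genomes.items()
        }
        pd.DataFrame.from_dict(rows, orient="index").to_csv(
            path, sep="\t", index_label="genome_id"
        )


def load_reference_collection(
    genomes_fasta: str | Path,
    lineage_table: str | Path,
    bpm_table: str | Path,
    categories_table: str | Path | None = None,
) -> tuple[ReferenceCollection, BinaryPhenotypeMatrix]:
    """Load and cross-validate the reference collection and its BPM.

    Validation problems (bad sequence characters, non-binary BPM cells,
    BPM rows without a genome) are aggregated and raised together as one
    :class:`ValidationError` so a malformed input reports every problem at
    once, with row/column coordinates.
    """
    problems: list[str] = []

    lineages = pd.read_csv(lineage_table, sep="\t", index_col="genome_id").fillna("")
    genomes: dict[str, ReferenceGenome] = {}
    for gid, row in lineages.iterrows():
        lineage = tuple(str(row.get(r, "")) for r in RANKS)
        if not any(lineage):
            problems.append(f"genome {gid!r}: lineage has no ranks")
        genomes[str(gid)] = ReferenceGenome(str(gid), lineage)

    for rec in SeqIO.parse(str(genomes_fasta), "fasta"):
        gid = sequence_genome_id(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            problems.append(f"sequence {rec.id!r}: empty")
        extra = set(seq) - _ALPHABET
        if extra:
            problems.append(
                f"sequence {rec.id!r}: characters outside ACGTN: {sorted(extra)}"
            )
        if gid not in genomes:
            problems.append(f"sequence {rec.id!r}: no lineage for genome {gid!r}")
            continue
        genomes[gid].sixteen_s[rec.id] = seq

    raw = pd.read_csv(bpm_table, sep="\t", index_col="genome_id")
    raw.index.name = None
    orphans = [g for g in raw.index if str(g) not in genomes]
    if orphans:
        problems.append(f"BPM rows without a reference genome: {orphans}")
    bad = raw.map(lambda v: v not in (0, 1))
    for g, p in zip(*bad.values.nonzero()):
        problems.append(
            f"non-binary BPM cell at genome={raw.index[g]!r}, "
            f"phenotype={raw.columns[p]!r}: {raw.iat[g, p]!r}"
        )

    if problems:
        raise ValidationError(problems)

    if categories_table is not None:
        categories = pd.read_csv(categories_table, sep="\t", index_col="phenotype_id")[
            "category"
        ]
    else:
        categories = pd.Series("GH family", index=raw.columns)
    bpm = BinaryPhenotypeMatrix(values=raw.astype(int), categories=categories)
    bpm.validate()
    return ReferenceCollection(genomes), bpm


def merge_bpm(
    metabolic: BinaryPhenotypeMatrix, gh: BinaryPhenotypeMatrix
) -> BinaryPhenotypeMatrix:
    """Column-concatenate a metabolic BPM with its GH-family counterpart.

    Requires the same genome set and disjoint phenotype ids; categories are
    carried through. Concatenating an empty matrix is the identity.
    """
    if gh.values.shape[1] == 0:
        return BinaryPhenotypeMatrix(metabolic.values.copy(), metabolic.categories.copy())
    if set(metabolic.genome_ids) != set(gh.genome_ids):
        only_a = set(metabolic.genome_ids) - set(gh.genome_ids)
        only_b = set(gh.genome_ids) - set(metabolic.genome_ids)
        raise ValueError(
            f"genome sets differ: only in metabolic {sorted(only_a)}, "
            f"only in GH {sorted(only_b)}"
        )
    overlap = metabolic.phenotype_ids.intersection(gh.phenotype_ids)
    if len(overlap):
        raise ValueError(f"overlapping phenotype ids: {list(overlap)}")
    values = pd.concat(
        [metabolic.values, gh.values.loc[metabolic.genome_ids]], axis=1
    )
    categories = pd.concat([metabolic.categories, gh.categories])
    merged = BinaryPhenotypeMatrix(values=values, categories=categories)
    merged.validate()
    return merged
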