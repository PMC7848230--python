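"""Multi-taxonomic assignment (MTA) of ASVs from alignment hits.

An ASV's representative sequence is aligned against the reference 16S
collection; hits are sorted by identity fraction F and the best identity is
M. Hits kept for assignment are those with

    F in [M - (1 - M)/S, M]   and   F > D

where S (default 4) narrows the accepted band as identities drop and D
(default 0.85) is the drop threshold below which the query stays
unassigned. The selected hits define

* an MTA: the set of unique taxonomic lineages with equal weights,
  rendered per rank as slash-joined, lexicographically sorted names
  ("Bacteroides ovatus/vulgatus" style) — slash-joined strings are
  distinct features, so A/B and A/B/C never merge; and
* a genome mapping: equal weights over the *distinct* genomes behind the
  selected hits (multiple 16S copies of one genome collapse to one entry,
  avoiding copy-number bias).

Both interval endpoints are inclusive; D is strict. A query whose best hit
fails D is unassigned: it contributes no taxonomic feature and no
phenotype probability, but its abundance still counts in the relative-
abundance denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import edlib
import pandas as pd

from .reference import RANKS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    identity: float  # fraction in [0, 1]

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity {self.identity} outside [0, 1]")


@dataclass(frozen=True)
class HitSelectionParams:
    """S and D of the top-hit selection rule."""

    scale: float = 4.0
    drop_threshold: float = 0.85

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale S must be positive")
        if not 0.0 <= self.drop_threshold <= 1.0:
            raise ValueError("drop threshold D must lie in [0, 1]")


@dataclass
class MultiTaxonomicAssignment:
    """Equal-weight set of lineages for one ASV, plus its string form."""

    asv_id: str
    lineages: list[tuple[str, ...]]
    string_form: tuple[str, ...] = field(init=False)  # per rank, "/".joined

    def __post_init__(self) -> None:
        self.string_form = tuple(
            "/".join(sorted({lin[i] for lin in self.lineages if lin[i]}))
            for i in range(len(RANKS))
        )

    @property
    def weight(self) -> float:
        return 1.0 / len(self.lineages)

    def rank_string(self, rank: str) -> str:
        return self.string_form[RANKS.index(rank)]


@dataclass
class GenomeMapping:
    """Equal weights over the distinct reference genomes of an ASV."""

    asv_id: str
    weights: dict[str, float]  # genome_id -> weight

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError("empty genome mapping; absent mappings use None")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {total}, expected 1")


def select_top_hits(
    hits: Sequence[AlignmentHit], params: HitSelectionParams = HitSelectionParams()
) -> list[AlignmentHit]:
    """Apply the [M-(1-M)/S, M] band and the F > D drop threshold.

    Returns [] for empty input or when the best hit fails D (unassigned).
    """
    if not hits:
        return []
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise ValueError(f"hits span multiple queries: {sorted(queries)}")
    m = max(h.identity for h in hits)
    if m <= params.drop_threshold:
        return []
    lower = m - (1.0 - m) / params.scale
    return [
        h
        for h in hits
        if h.identity >= lower and h.identity > params.drop_threshold
    ]


def build_mta(
    selected_hits: Sequence[AlignmentHit],
    lineage_lookup: Callable[[str], tuple[str, ...]],
) -> MultiTaxonomicAssignment:
    """Collapse the selected hits' lineages into an equal-weight MTA."""
    if not selected_hits:
        raise ValueError("build_mta requires at least one selected hit")
    lineages: list[tuple[str, ...]] = []
    for h in selected_hits:
        try:
            lin = tuple(lineage_lookup(h.subject_id))
        except KeyError as err:
            raise KeyError(
                f"subject {h.subject_id!r} of query {h.query_id!r} has no lineage"
            ) from err
        if lin not in lineages:
            lineages.append(lin)
    return MultiTaxonomicAssignment(selected_hits[0].query_id, lineages)


def map_asv_to_genomes(
    hits: Sequence[AlignmentHit],
    subject_to_genome: Callable[[str], str],
    params: HitSelectionParams = HitSelectionParams(),
) -> GenomeMapping | None:
    """Map one ASV to reference genomes via the same top-hit selection.

    Weights are equal over distinct genomes after collapsing multiple 16S
    copies. Returns None when no hit passes (downstream leaves the
    phenotype probability undefined for the ASV).
    """
    selected = select_top_hits(hits, params)
    if not selected:
        return None
    genomes = sorted({subject_to_genome(h.subject_id) for h in selected})
    w = 1.0 / len(genomes)
    return GenomeMapping(selected[0].query_id, {g: w for g in genomes})


def naive_identity(query_seq: str, subject_seq: str) -> float:
    """Global-alignment identity fraction of two nucleotide sequences.

    Unit-cost global (Needleman–Wunsch) edit distance d, reported as
    1 - d / max(len). Deterministic; the test-scale stand-in for an
    external aligner's percent identity.
    """
    if not query_seq or not subject_seq:
        raise ValueError("sequences must be nonempty")
    d = edlib.align(query_seq, subject_seq, mode="NW")["editDistance"]
    return 1.0 - d / max(len(query_seq), len(subject_seq))


def aggregate_genus_features(
    asv_table: pd.DataFrame,
    mta_per_asv: Mapping[str, MultiTaxonomicAssignment],
) -> pd.DataFrame:
    """Sum ASV abundances onto genus-level MTA string features.

    ``asv_table`` is samples x ASVs. ASVs without an MTA, or whose MTA has
    no genus-rank name, are excluded (logged); note distinct slash-joined
    strings stay distinct features. Columns are sorted by name.
    """
    if asv_table.shape[1] == 0:
        return asv_table.copy()
    groups: dict[str, list[str]] = {}
    dropped = []
    for asv in asv_table.columns:
        mta = mta_per_asv.get(asv)
        genus = mta.rank_string("genus") if mta is not None else ""
        if not genus:
            dropped.append(asv)
            continue
        groups.setdefault(genus, []).append(asv)
    if dropped:
        logger.info(
            "aggregate_genus_features: %d ASVs without genus-level MTA excluded",
            len(dropped),
        )
    data = {
        genus: asv_table[cols].sum(axis=1) for genus, cols in sorted(groups.items())
    }
    return pd.DataFrame(data, index=asv_table.index)


def load_hit_table(path: str | Path, percent: bool = False) -> pd.DataFrame:
    """Read a hit TSV (query_id, subject_id, identity).

    With ``percent=True`` identities are divided by 100 on load (outfmt-6
    style pident columns).
    """
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:3]) == ["qseqid", "sseqid", "pident"]:
        df = df.rename(
            columns={"qseqid": "query_id", "sseqid": "subject_id", "pident": "identity"}
        )
        percent = True
    df = df[["query_id", "subject_id", "identity"]].copy()
    if percent:
        df["identity"] = df["identity"] / 100.0
    return df


def hits_by_query(hit_table: pd.DataFrame) -> dict[str, list[AlignmentHit]]:
    """Group a hit table into per-query AlignmentHit lists."""
    out: dict[str, list[AlignmentHit]] = {}
    for row in hit_table.itertuples(index=False):
        out.setdefault(row.query_id, []).append(
            AlignmentHit(row.query_id, row.subject_id, float(row.identity))
        )
    return out
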