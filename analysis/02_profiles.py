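#!/usr/bin/env python
"""Assign ASVs and compute taxonomy / CPI / PAD profiles for each cohort.

Reads the study layout written by 01_simulate.py (or any data prepared in
the same formats), runs multi-taxonomic assignment and genome mapping
from the alignment-hit table, applies the coverage and ASV-retention
filters, and writes per-cohort genus-abundance, CPI and PAD tables under
--out (default results/profiles/).
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

from phenomark import pipeline
from phenomark.mta import load_hit_table
from phenomark.profiles import read_asv_dataset, write_profile
from phenomark.reference import load_reference_collection


def load_datasets(data_dir: Path):
    labels = pd.read_csv(data_dir / "labels.tsv", sep="\t")
    out = []
    for ds_id in sorted(labels["dataset_id"].unique()):
        out.append(read_asv_dataset(
            ds_id,
            data_dir / f"{ds_id}_abundance.tsv",
            data_dir / f"{ds_id}_rep_seqs.fasta",
            data_dir / "labels.tsv",
        ))
    return out


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("data"))
    ap.add_argument("--out", type=Path, default=Path("results/profiles"))
    ap.add_argument("--min-reads", type=int, default=pipeline.DEFAULT_MIN_READS)
    args = ap.parse_args(argv)

    collection, bpm = load_reference_collection(
        args.data / "reference_16s.fasta",
        args.data / "reference_lineages.tsv",
        args.data / "bpm.tsv",
        args.data / "bpm_categories.tsv",
    )
    hits = load_hit_table(args.data / "hits.tsv")
    datasets = load_datasets(args.data)

    assignments = pipeline.assign_asvs(hits, collection, bpm)
    n_mapped = sum(m is not None for m in assignments.mappings.values())
    print(f"assigned {len(assignments.mtas)} / {len(assignments.mappings)} "
          f"ASVs an MTA; {n_mapped} mapped to genomes")

    study = pipeline.build_study(datasets, assignments,
                                 min_reads=args.min_reads)
    args.out.mkdir(parents=True, exist_ok=True)
    for d in study.dataset_ids:
        write_profile(study.features["taxonomy"][d],
                      args.out / f"{d}_genus_abundance.tsv")
        write_profile(study.features["phenotype"][d], args.out / f"{d}_cpi.tsv")
        write_profile(study.pad[d], args.out / f"{d}_pad.tsv")
        cpi = study.features["phenotype"][d]
        print(f"cohort {d}: {study.features['taxonomy'][d].shape[1]} genus "
              f"features, {cpi.shape[1]} phenotypes, "
              f"{cpi.shape[0]} samples; mean PAD "
              f"{study.pad[d].mean().mean():.2f}")
    print(f"wrote {args.out}/")
    return 0


if __name__ == "__main__":
    sys.exit(main())
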