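#!/usr/bin/env python
"""Generate the synthetic multi-cohort study the later steps analyse.

Writes, under --out (default data/): the reference 16S FASTA, lineage
table, binary phenotype matrix with its category sidecar, per-cohort
abundance tables and rep-seq FASTAs, sample labels, the alignment-hit
table, and a ground-truth JSON recording the planted effects.

The default conditions are three cohorts of 60 HC / 30 CD / 30 UC
samples over 300 ASVs from 150 reference genomes, with one planted case
effect: carriers of the diffuse phenotype ``phen_rand_01`` are enriched
4-fold in CD and UC samples. Pass --scenario to override with a YAML
scenario file, --null to drop the planted effects.
"""

import argparse
import sys
from dataclasses import replace
from pathlib import Path

from phenomark.simulate import (
    PlantedEffect,
    SyntheticScenario,
    asv_sequences,
    generate_datasets,
    generate_hits,
    generate_reference,
    scenario_from_yaml,
    scenario_to_yaml,
    write_scenario_data,
)

DEFAULT_EFFECTS = (
    PlantedEffect("phenotype", "phen_rand_01", "enrich", 2.0, ("CD", "UC")),
)


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("data"))
    ap.add_argument("--scenario", type=Path, default=None,
                    help="YAML scenario file overriding the defaults")
    ap.add_argument("--null", action="store_true",
                    help="drop all planted effects (control study)")
    args = ap.parse_args(argv)

    if args.scenario:
        scenario = replace(scenario_from_yaml(args.scenario), seed=args.seed)
    else:
        scenario = SyntheticScenario(seed=args.seed,
                                     planted_effects=DEFAULT_EFFECTS)
    if args.null:
        scenario = replace(scenario, planted_effects=())

    bundle, truth = generate_reference(scenario)
    datasets = generate_datasets(scenario, bundle, truth)
    seqs = asv_sequences(scenario, bundle, truth)
    hits = generate_hits(seqs, bundle.collection.all_sequences())

    args.out.mkdir(parents=True, exist_ok=True)
    write_scenario_data(scenario, bundle, truth, datasets, args.out)
    hits.to_csv(args.out / "hits.tsv", sep="\t", index=False)
    scenario_to_yaml(scenario, args.out / "scenario.yaml")

    print(f"reference: {len(bundle.collection)} genomes, "
          f"{bundle.bpm.values.shape[1]} phenotypes")
    for ds in datasets:
        counts = ds.labels.value_counts().to_dict()
        print(f"cohort {ds.dataset_id}: {len(ds.sample_ids)} samples {counts}")
    print(f"hit table: {len(hits)} alignments for {len(seqs)} ASVs")
    for e in scenario.planted_effects:
        print(f"planted: {e.direction} {e.target_kind} {e.target_id} "
              f"(2^{e.log2_fc}x) in {'/'.join(e.statuses)}")
    print(f"wrote {args.out}/")
    return 0


if __name__ == "__main__":
    sys.exit(main())
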