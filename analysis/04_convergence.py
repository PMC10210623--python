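#!/usr/bin/env python
"""Cross-species convergent amino-acid substitution detection.

Builds the ALK/FW population consensus proteins for the rhcg-like gene from
the genotype data, scans the ortholog protein alignment for differentiating
and convergent columns, and compares the detected set against the planted
truth.

Outputs: results/convergence.json. Run analysis/01_simulate.py first.
"""

import json
from pathlib import Path

import pandas as pd

from alkscan import io as gio
from alkscan.pipeline import load_inputs
from alkscan.convergence import (build_population_consensus,
                                 detect_convergent_sites, report_convergence)

FIXTURE = Path("scratch/fixture")
RESULTS = Path("results")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    truth = json.loads((FIXTURE / "truth.json").read_text())
    inputs = load_inputs(FIXTURE)

    rhcg = next(g for g in inputs.genes if g.gene_id == "rhcg_like")
    prot = build_population_consensus(rhcg, inputs.genomes[rhcg.chrom],
                                      inputs.table)
    diffs = [i + 1 for i, (a, b) in enumerate(zip(prot["ALK"], prot["FW"]))
             if a != b]
    print(f"population consensus proteins differ at residues {diffs}")

    alignment = {s.name: s.residues
                 for s in gio.read_fasta(FIXTURE / "ortholog.aln.fa")}
    roles = dict(pd.read_csv(FIXTURE / "roles.tsv", sep="\t",
                             header=None).values)
    sites = detect_convergent_sites(alignment, roles)
    rep = report_convergence(sites, gene_id="rhcg_like",
                             cds_parts=rhcg.cds_parts)
    (RESULTS / "convergence.json").write_text(json.dumps(rep, indent=2) + "\n")

    print(f"{rep['n_differentiating']} differentiating columns, "
          f"{rep['n_convergent']} convergent "
          f"(truth: {len(truth['ortholog']['differentiating_columns'])} / "
          f"{len(truth['ortholog']['convergent_columns'])})")
    for c in rep["columns"]:
        if c["status"] == "convergent":
            print(f"  column {c['column']}: {c['substitution']} shared by "
                  f"{', '.join(c['supporting_species'])}")


if __name__ == "__main__":
    main()
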