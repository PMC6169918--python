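"""Audit per-sample coverage sufficiency and call undercovered cohorts.

From the per-sample coverage table: which gene x cohort cells have more than
75% of samples below the 25x average-depth threshold? Writes the undercovered
pairs and the gene x cohort sufficiency matrix (cohorts with a called
mutation in a gene are marked not_considered).
"""

import argparse
from pathlib import Path

from capaudit.coverage import read_coverage_tsv, undercovered_cohort
from capaudit.kits import status_matrix, write_status_matrix
from capaudit.maf import build_cohort_table, read_maf, read_roster
from capaudit.simulate import GroundTruth

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/synthetic"))
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()

rows = read_coverage_tsv(args.data / "coverage.tsv")
rosters = read_roster(args.data / "roster.tsv")
tables = {
    p.stem: build_cohort_table(read_maf(p, p.stem), rosters[p.stem], p.stem)
    for p in sorted(args.data.glob("*.maf"))
}

flags: dict[tuple[str, str], list[bool]] = {}
for r in rows:
    flags.setdefault((r.gene_symbol, r.cohort_id), []).append(r.sufficient)
under = sorted(k for k, fl in flags.items() if undercovered_cohort(fl))

args.out_dir.mkdir(parents=True, exist_ok=True)
with (args.out_dir / "undercovered_cohorts.tsv").open("w") as fh:
    fh.write("gene_symbol\tcohort\n")
    for gene, cohort in under:
        fh.write(f"{gene}\t{cohort}\n")

genes = sorted({r.gene_symbol for r in rows})
write_status_matrix(status_matrix(rows, tables, genes), args.out_dir / "status_matrix.tsv")

truth = GroundTruth.from_json(args.data / "ground_truth.json")
absent = set(truth.absent["kit_biased"])
n_absent_pairs = sum(1 for g, c in under if g in absent)
print(f"{len(rows)} coverage rows over {len(genes)} genes")
print(f"undercovered gene x cohort pairs: {len(under)} -> {args.out_dir / 'undercovered_cohorts.tsv'}")
print(f"  of which planted absent genes on their kit's cohorts: {n_absent_pairs} (expect {3 * len(absent)})")
print(f"status matrix -> {args.out_dir / 'status_matrix.tsv'}")
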