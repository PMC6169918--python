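"""Audit the capture-design BEDs against the gene models.

Per kit and region mode (whole exons vs coding sequence only): how many
genes have less than 80% of their bases inside the kit's merged targets, and
of those, how many have no overlap at all (absent probes)? Statuses are
compared against the planted design ground truth.
"""

import argparse
from pathlib import Path

from capaudit.design import audit_design, write_audit_tsv
from capaudit.intervals import read_bed, read_gene_models
from capaudit.simulate import GroundTruth

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/synthetic"))
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()

models = read_gene_models(args.data / "gene_models.tsv")
truth = GroundTruth.from_json(args.data / "ground_truth.json")
args.out_dir.mkdir(parents=True, exist_ok=True)

for bed in sorted(args.data.glob("design_*.bed")):
    kit = bed.stem.removeprefix("design_")
    design = read_bed(bed, kit)
    for mode in ("exon", "cds"):
        rows, summary = audit_design(design, models, mode)
        out = args.out_dir / f"design_audit_{kit}_{mode}.tsv"
        write_audit_tsv(rows, out, kit_name=kit)
        mismatches = [
            r.gene_symbol
            for r in rows
            if mode == "exon" and r.status != truth.design_status(kit, r.gene_symbol)
        ]
        print(
            f"{kit} ({mode}): {summary['n_genes']} genes scored, "
            f"{summary['n_undercovered']} undercovered "
            f"({summary['undercovered_absent']} absent, "
            f"{summary['undercovered_incomplete']} incomplete), "
            f"{len(summary['skipped_no_cds'])} skipped -> {out}"
        )
        if mode == "exon":
            print(f"  statuses match planted truth: {not mismatches}")
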