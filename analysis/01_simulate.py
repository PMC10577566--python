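"""Generate the synthetic depletion-time-course dataset with ground truth.

Writes, under --out: gene and peak BED files, the peak x sample ATAC count
matrix, nascent-RNA fragments, per-peak FASTA sequences, and the truth
tables that later stages are scored against.

Usage: python analysis/01_simulate.py --seed 1 --out results/sim
"""

import argparse
from pathlib import Path

from importlib import resources

from pioneerdyn import motifs as mf, synthetic as syn
from pioneerdyn.io_core import write_bed


def run(seed: int, out: Path, small: bool = False) -> syn.SimConfig:
    out.mkdir(parents=True, exist_ok=True)
    if small:
        cfg = syn.SimConfig(
            seed=seed, n_chroms=1, chrom_length=1_000_000, n_genes=20,
            n_peaks=200, timepoints=(0.0, 2.0),
        )
    else:
        cfg = syn.SimConfig(seed=seed)
    genes = syn.simulate_annotation(cfg)
    peaks, counts, truth = syn.simulate_peaks_and_timecourse(cfg, genes)
    labels = syn.simulate_deg_link(cfg, genes, peaks, truth)
    frags = syn.simulate_ttseq_coverage(cfg, genes, labels)
    pwm = mf.read_jaspar(
        str(resources.files("pioneerdyn") / "data" / "sox_like_synthetic.jaspar")
    )[0]
    seqs = syn.simulate_sequences(cfg, peaks, truth, pwm.probabilities)

    write_bed(genes, out / "genes.bed")
    write_bed(peaks, out / "peaks.bed")
    counts.to_tsv(out / "atac_counts.tsv")
    truth.peaks.to_csv(out / "truth_peaks.tsv", sep="\t")
    labels.to_csv(out / "truth_genes.tsv", sep="\t")
    truth.sequences.to_csv(out / "truth_sequences.tsv", sep="\t")
    frags.to_csv(out / "ttseq_fragments.tsv", sep="\t", index=False)
    syn.write_fasta(seqs, out / "peak_sequences.fa")

    n_down = (labels.deg_status == "down").sum()
    print(
        f"simulated {len(genes)} genes / {len(peaks)} peaks on "
        f"{cfg.n_chroms} chromosomes; {n_down} down-DEGs "
        f"({n_down / len(genes):.0%}); {len(frags)} nascent fragments"
    )
    return cfg


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/sim"))
    ap.add_argument("--small", action="store_true",
                    help="reduced problem size (quick checks)")
    args = ap.parse_args()
    run(args.seed, args.out, args.small)
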