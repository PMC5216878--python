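"""Generate the two synthetic study panels used by the downstream analyses.

Writes to results/datasets/:
  neutral/  49 loci under the domestication demography, no sweeps
  swept/    40 loci with four strong injected sweeps (retention 0.05)

Both panels carry 19 wild (MW) and 20 domesticated (MD) haploid inbred
accessions, exon/intron mosaic structures and a truth record.
"""

from pathlib import Path

from beanscan.seqdata import write_dataset
from beanscan.synthetic_data import (
    GeneratorConfig,
    SweepSpec,
    generate_dataset,
    write_truth,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "datasets"


def main() -> None:
    neutral_cfg = GeneratorConfig(n_loci=49, seed=2026)
    swept_cfg = GeneratorConfig(
        n_loci=40, seed=2027,
        sweeps=SweepSpec(loci=("SYN-L01", "SYN-L02", "SYN-L03", "SYN-L04"),
                         retention=0.05))
    for name, cfg in (("neutral", neutral_cfg), ("swept", swept_cfg)):
        dataset, truth = generate_dataset(cfg)
        outdir = OUT / name
        write_dataset(dataset, outdir)
        write_truth(truth, outdir)
        n_ann = len(dataset.annotations)
        print(f"{name}: {len(dataset.loci)} loci ({n_ann} annotated, "
              f"{len(truth.swept_loci)} swept) -> {outdir}")


if __name__ == "__main__":
    main()
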