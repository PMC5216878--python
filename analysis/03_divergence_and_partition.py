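"""Divergence analyses on the neutral synthetic panel: per-locus Hudson FST
with permutation tests, the shared/private mutation partition with the
binomial test on domesticated-private coding mutations, per-locus dN/dS with
the paired signed-rank test, and the private-replacement report.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from beanscan.codon_partition import (
    CodingDataError,
    NoInformativePairsError,
    binomial_private_coding_test,
    nei_gojobori_dn_ds,
    paired_wilcoxon_dnds,
    partition_polymorphisms,
    private_replacement_report,
)
from beanscan.differentiation import UndefinedFstError, fst_permutation_test
from beanscan.diversity import region_alignment
from beanscan.seqdata import (
    EmptyRegionError,
    PopulationLabel,
    read_dataset,
    slice_region,
    usable_sites,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 2028


def main() -> None:
    dataset = read_dataset(ROOT / "datasets" / "neutral")
    out = ROOT / "divergence"
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)

    # FST with permutation tests, shaped like the per-locus report
    fst_rows = []
    for aln in dataset.loci:
        row = {"locus": aln.locus_id}
        for region in ("whole", "coding", "noncoding"):
            try:
                reg = region_alignment(dataset, aln, region)
                w = dataset.population(reg, PopulationLabel.MW)
                d = dataset.population(reg, PopulationLabel.MD)
                f, p = fst_permutation_test(
                    w, d, n_perm=1000, seed=int(rng.integers(1, 2 ** 31)))
                row[f"fst_{region}"], row[f"p_{region}"] = round(f, 3), p
            except EmptyRegionError:
                row[f"fst_{region}"] = "/"
            except UndefinedFstError:
                row[f"fst_{region}"] = "na"
        fst_rows.append(row)
    fst = pd.DataFrame(fst_rows)
    fst.to_csv(out / "fst_per_locus.tsv", sep="\t", index=False)
    numeric = pd.to_numeric(fst.fst_whole, errors="coerce")
    sig = pd.to_numeric(fst.get("p_whole"), errors="coerce") < 0.05
    print(f"mean whole-sequence FST = {numeric.mean():.3f}; "
          f"{int(sig.sum())}/{int(numeric.notna().sum())} loci significant "
          "at P<0.05 (1000 permutations)")

    # shared/private partition and the binomial test
    totals = {"coding": None, "noncoding": None}
    agg = {}
    for aln in dataset.loci:
        w = dataset.population(aln, PopulationLabel.MW)
        d = dataset.population(aln, PopulationLabel.MD)
        part = partition_polymorphisms(
            w, d, dataset.annotations.get(aln.locus_id))
        for region, cc in part.by_region.items():
            cur = agg.setdefault(region, [0, 0, 0, 0])
            cur[0] += cc.shared
            cur[1] += cc.private_wild
            cur[2] += cc.private_dom
            cur[3] += part.region_lengths.get(region, 0)
    table = pd.DataFrame(
        [{"region": r, "shared": v[0], "private_wild": v[1],
          "private_dom": v[2], "length": v[3]} for r, v in agg.items()])
    table.to_csv(out / "partition_totals.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    pooled = {
        "private_wild_coding": int(table.set_index("region").loc[
            "coding", "private_wild"]),
        "private_wild_noncoding": int(table.set_index("region").loc[
            "noncoding", "private_wild"]),
        "private_dom_coding": int(table.set_index("region").loc[
            "coding", "private_dom"]),
        "private_dom_noncoding": int(table.set_index("region").loc[
            "noncoding", "private_dom"]),
        "region_lengths": {
            "coding": int(table.set_index("region").loc["coding", "length"]),
            "noncoding": int(table.set_index("region").loc[
                "noncoding", "length"])},
    }
    try:
        p = binomial_private_coding_test(pooled)
        print(f"binomial test (raw-count null) for excess private-MD coding "
              f"mutations: P = {p:.3f}")
    except ValueError as exc:
        print(f"binomial test not computable: {exc}")

    # dN/dS per locus and the paired test
    dnds_rows = []
    for aln in dataset.loci:
        ann = dataset.annotations.get(aln.locus_id)
        if ann is None or "exon" not in ann.classes_present:
            continue
        exon = slice_region(aln, ann, {"exon"})
        mask = usable_sites(exon).usable
        cols = [j for j in range(ann.frame_offset, exon.length) if mask[j]]
        cols = cols[:3 * (len(cols) // 3)]
        if len(cols) < 9:
            continue
        row = {"locus": aln.locus_id}
        try:
            for label in (PopulationLabel.MW, PopulationLabel.MD):
                pop = dataset.population(exon, label).columns(cols)
                est = nei_gojobori_dn_ds(
                    list(pop.rows.values()), n_boot=200,
                    seed=int(rng.integers(1, 2 ** 31)))
                row[f"dN_{label.value}"] = est.dN
                row[f"dS_{label.value}"] = est.dS
        except CodingDataError:
            continue
        dnds_rows.append(row)
    dnds = pd.DataFrame(dnds_rows).dropna()
    dnds.to_csv(out / "dnds_per_locus.tsv", sep="\t", index=False)
    try:
        _, p = paired_wilcoxon_dnds(
            dnds.dN_MW - dnds.dS_MW, dnds.dN_MD - dnds.dS_MD,
            alternative="greater")
        print(f"paired signed-rank test, (dN-dS) MD > MW over "
              f"{len(dnds)} loci: P = {p:.3f}")
    except NoInformativePairsError:
        print("paired dN/dS test: no informative pairs")

    # private replacement changes
    recs = private_replacement_report(dataset)
    rep = pd.DataFrame([{
        "locus": r.locus_id, "codon": r.variant_codon,
        "background": r.background_codon,
        "aa_change": f"{r.background_aa}->{r.variant_aa}",
        "n_md_carriers": len(r.carriers["MD"]), "derived": r.derived,
    } for r in recs])
    rep.to_csv(out / "private_replacements.tsv", sep="\t", index=False)
    print(f"{len(rep)} replacement changes private to MD")


if __name__ == "__main__":
    main()
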