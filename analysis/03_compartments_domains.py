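#!/usr/bin/env python
"""Compartments, saddle strengths, insulation boundaries and the IZ test.

Recovers the planted A/B blocks from the correlation-matrix eigenvector,
quantifies compartment strength from saddle corners, calls TAD
boundaries from diamond insulation, classifies dot vs dotless domains
against the planted loops, and runs the compartment-matched IZ
resampling test with boundary categories as targets.
"""

import json

import numpy as np
import pandas as pd

import common
from common import DATA, SEED, TABLES
from nucleome import io
from nucleome.compartments import (
    call_compartment_domains,
    compartment_eigenvector,
    saddle_result,
)
from nucleome.domains import (
    call_boundaries,
    classify_dot_domains,
    coregistration,
    insulation_score,
    iz_resampling_test,
)


def main():
    common.ensure_dirs()
    layout = io.read_bin_table(DATA / "bins_500.tsv")
    truth = json.loads((DATA / "truth_maps.json").read_text())
    comp = np.asarray(truth["compartments"])

    cm = io.read_contacts_coo(DATA / "contacts_ab.tsv", layout)
    prof = compartment_eigenvector(cm, comp.astype(float))
    acc = (prof.labels == comp).mean()
    io.write_bedgraph(layout, np.nan_to_num(prof.eigenvector),
                      TABLES / "compartment_ev.bedgraph")
    print(f"compartment eigenvector label accuracy vs planted: {acc:.3f}")

    sr = saddle_result(cm, prof, n_quantile_bins=20)
    print(f"compartment strength at planted 1.5: AA={sr.aa_strength:.3f}, "
          f"BB={sr.bb_strength:.3f} (null level 0.5)")
    doms = pd.DataFrame(call_compartment_domains(prof, layout))
    doms.to_csv(TABLES / "compartment_domains.tsv", sep="\t", index=False)
    print(f"{len(doms)} compartment domains, median size "
          f"{doms['size'].median()/1e6:.1f} Mb")

    # insulation + boundaries on the TAD map
    cm_tad = io.read_contacts_coo(DATA / "contacts_tad.tsv", layout)
    ins = insulation_score(cm_tad, window_bins=5)
    io.write_bedgraph(layout, np.nan_to_num(ins.log2_insulation),
                      TABLES / "insulation.bedgraph")
    bd = call_boundaries(ins, layout, min_strength=0.1)
    bd.to_csv(TABLES / "boundaries.tsv", sep="\t", index=False)
    planted_b = np.asarray(truth["tad_boundaries"])
    called = bd["bin"].to_numpy()
    recall = np.mean([np.abs(called - b).min() <= 1 for b in planted_b])
    print(f"boundary recovery: {len(called)} called, recall {recall:.2f} "
          f"within 1 bin of {len(planted_b)} planted")

    # dot / dotless classification of the inter-boundary domains
    starts = np.concatenate([[0], planted_b]) * layout.bin_size
    ends = np.concatenate([planted_b, [layout.n_bins]]) * layout.bin_size
    doms_tad = pd.DataFrame({"chrom": "chr1", "start": starts, "end": ends})
    loops_t = pd.DataFrame(truth["loops"])
    bs = layout.bin_size
    loop_df = pd.DataFrame({
        "chrom": "chr1",
        "start1": np.asarray(loops_t["bin1"]) * bs,
        "end1": (np.asarray(loops_t["bin1"]) + 1) * bs,
        "start2": np.asarray(loops_t["bin2"]) * bs,
        "end2": (np.asarray(loops_t["bin2"]) + 1) * bs})
    dots = classify_dot_domains(doms_tad, loop_df)
    print(f"dot domains: {int(dots.sum())}/{len(dots)} "
          f"(loops were planted independently of the TAD grid)")

    # co-registration of called compartment domains with planted blocks
    planted_blocks = []
    lab = comp
    start = 0
    for i in range(1, len(lab) + 1):
        if i == len(lab) or lab[i] != lab[start]:
            planted_blocks.append(("chr1", start * bs, i * bs))
            start = i
    rel = coregistration(doms[["chrom", "start", "end"]],
                         pd.DataFrame(planted_blocks,
                                      columns=["chrom", "start", "end"]))
    frac = (rel["relation"] == "co-register").mean()
    print(f"called domains co-registering (J>0.7) with planted blocks: {frac:.2f}")

    # IZ resampling test: IZs planted on dot-domain corners
    rng = np.random.default_rng(SEED + 3)
    comp_df = pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(0, 100_000_000, 5_000_000),
        "end": np.arange(0, 100_000_000, 5_000_000) + 5_000_000,
        "label": np.where(np.arange(20) % 2 == 0, "A", "B")})
    cats = {
        "boundary": pd.DataFrame({
            "chrom": "chr1", "start": planted_b * bs - 50_000,
            "end": planted_b * bs + 50_000}),
        "interior": pd.DataFrame({
            "chrom": "chr1", "start": planted_b * bs + 2_000_000 - 50_000,
            "end": planted_b * bs + 2_000_000 + 50_000}).query("end < 100_000_000"),
    }
    on_boundary = planted_b[:: 2] * bs - 10_000
    izs = pd.DataFrame({"chrom": "chr1", "start": on_boundary,
                        "end": on_boundary + 50_000})
    res = iz_resampling_test(izs, cats, comp_df, n_resamples=10_000,
                             seed=int(rng.integers(2**31)))
    for name, r in res.items():
        print(f"IZ test [{name}]: observed {r['observed']:.2f}, "
              f"null mean {r['null_mean']:.3f}, p = {r['p']:.2e}")
    pd.DataFrame(res).T.to_csv(TABLES / "iz_test.tsv", sep="\t")


if __name__ == "__main__":
    main()
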