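#!/usr/bin/env python
"""Loop integration, APA, consensus clustering and enrichment.

Merges multi-resolution loop calls with the union rule, measures APA and
mean loop strength on the loop-spiked map, clusters the 2,000 simulated
loops by anchor chromatin-state signatures, scores state-pair and TF
enrichment against shuffle nulls, and links genes to enhancers through
loop anchors with the expression-breadth pipeline.
"""

import json

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

import common
from common import DATA, SEED, TABLES
from nucleome import io
from nucleome.loops import (
    anchor_state_features,
    apa,
    classify_ep_sharing,
    cluster_loops,
    expression_breadth,
    expression_quartiles,
    link_genes_to_enhancers,
    loop_state_pair_enrichment,
    mean_loop_strength,
    merge_loops,
)


def main():
    common.ensure_dirs()
    layout = io.read_bin_table(DATA / "bins_500.tsv")
    truth = json.loads((DATA / "truth_maps.json").read_text())
    bs = layout.bin_size
    loops_t = pd.DataFrame(truth["loops"])
    planted_loops = pd.DataFrame({
        "chrom": "chr1",
        "start1": np.asarray(loops_t["bin1"]) * bs,
        "end1": (np.asarray(loops_t["bin1"]) + 1) * bs,
        "start2": np.asarray(loops_t["bin2"]) * bs,
        "end2": (np.asarray(loops_t["bin2"]) + 1) * bs})

    # union merge of two jittered "platforms" calling the same loops
    rng = np.random.default_rng(SEED + 4)
    fine = planted_loops.copy()
    fine["resolution"] = 5_000
    fine["platform"] = "micro-c"
    coarse = planted_loops.copy()
    jitter = rng.integers(-10_000, 10_000, len(coarse))
    coarse[["start1", "end1"]] = coarse[["start1", "end1"]].add(jitter, axis=0)
    coarse["resolution"] = 10_000
    coarse["platform"] = "hic"
    union = merge_loops([fine, coarse])
    print(f"loop union: {len(fine) + len(coarse)} calls from 2 platforms -> "
          f"{len(union)} merged loops "
          f"({(union['resolution'] == 5000).mean():.0%} represented at 5 kb)")
    io.write_bedpe(union, TABLES / "loops_union.bedpe")

    cm = io.read_contacts_coo(DATA / "contacts_loops.tsv", layout)
    res = apa(cm, planted_loops)
    strength = mean_loop_strength(planted_loops, cm)
    print(f"APA score {res['score']:.2f} over {res['n_loops']} loops "
          f"(planted factor 3); mean pixel O/E {strength:.2f}")

    # anchor-state clustering
    loops = io.read_bedpe(DATA / "loops.bedpe")
    segs = io.read_bed(DATA / "chromatin_states.bed",
                       names=["chrom", "start", "end", "state"])
    planted_cluster = np.loadtxt(DATA / "loops_planted_cluster.txt", dtype=int)
    feats = anchor_state_features(loops, segs)
    labels = cluster_loops(feats["matrix"], k_grid=tuple(range(50, 501, 50)),
                           seed=0)
    ari = adjusted_rand_score(planted_cluster, labels)
    print(f"consensus clustering: {len(np.unique(labels))} clusters, "
          f"ARI vs planted = {ari:.3f}")
    pd.DataFrame({"cluster": labels}).to_csv(TABLES / "loop_clusters.tsv",
                                             sep="\t", index=False)

    # state-pair enrichment of one planted cluster vs shuffle null
    chrom_lengths = {"chr1": 120_000_000, "chr2": 80_000_000}
    sub = loops[labels == labels[0]]
    enr = loop_state_pair_enrichment(sub, segs, chrom_lengths,
                                     n_controls=200, seed=SEED)
    enr.to_csv(TABLES / "loop_state_enrichment.tsv", sep="\t", index=False)
    top = enr.replace(np.inf, np.nan).nlargest(1, "fold").iloc[0]
    print(f"top state pair for cluster 0: ({top.state1}, {top.state2}) "
          f"fold {top.fold:.1f}")

    # enhancer-promoter linking + expression breadth
    tss = pd.DataFrame({"chrom": "chr1",
                        "pos": planted_loops["start1"] + 5_000,
                        "gene": [f"g{i}" for i in range(len(planted_loops))]})
    enh = pd.DataFrame({"chrom": "chr1",
                        "start": planted_loops["start2"],
                        "end": planted_loops["end2"]})
    pairs = link_genes_to_enhancers(planted_loops, tss, enh)
    print(f"E-P links: {len(pairs)} pairs, median distance "
          f"{pairs['distance'].median()/1e3:.0f} kb")
    half = pairs.iloc[: len(pairs) // 2]
    share = classify_ep_sharing(pairs, half)
    print(f"sharing with a half-subsampled second cell type: "
          f"{share['shared_fraction']:.0%} shared")

    tpm = pd.read_csv(DATA / "expression_tpm.tsv", sep="\t", index_col=0)
    planted_breadth = np.loadtxt(DATA / "expression_planted_breadth.txt", dtype=int)
    breadth = expression_breadth(tpm)
    hk = planted_breadth == tpm.shape[1]
    print(f"expression breadth: {int((breadth[hk] == tpm.shape[1]).sum())}"
          f"/{int(hk.sum())} housekeeping genes at full breadth")
    quart = expression_quartiles(tpm.iloc[:, 0])
    print(f"expression classes in tissue0: {quart.value_counts().to_dict()}")
    pd.DataFrame({"breadth": breadth, "class_t0": quart}).to_csv(
        TABLES / "expression_breadth.tsv", sep="\t")


if __name__ == "__main__":
    main()
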