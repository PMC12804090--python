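#!/usr/bin/env python
"""Generate the synthetic study inputs with planted, recorded truth.

Writes, under results/data/:
  - a 500-bin contact map with planted A/B blocks (strength 1.5), a
    TAD-structured map (strength 3) and a loop-spiked map (factor 3),
    as COO triplet TSV + bin table;
  - a diploid structure population in a 5-um sphere with planted
    speckles/nucleoli (coordinate TSV + JSON sidecar), its GAM
    segregation table, and speckle/lamina tracks as bedGraph;
  - a 2,000-loop BEDPE with planted anchor-state signatures and the
    chromatin-state segmentation BED;
  - an expression table across 12 tissues with planted breadth;
  - every planted truth as JSON next to the data.
"""

import json

import numpy as np

import common
from common import DATA, SEED
from nucleome import io
from nucleome.layout import make_genome
from nucleome.simdata import (
    NuclearGeometry,
    plant_truth,
    simulate_contact_map,
    simulate_expression,
    simulate_gam,
    simulate_loops_with_states,
    simulate_structures,
    simulate_tracks,
)


def main():
    common.ensure_dirs()
    rng = np.random.default_rng(SEED)

    layout = make_genome(common.CHROM_LENGTHS, common.BIN_SIZE)
    io.write_bin_table(layout, DATA / "bins_500.tsv")

    truth_ab = plant_truth(layout, block_bins=25, tad_bins=10**6)
    cm_ab = simulate_contact_map(layout, truth_ab, depth=common.DEPTH,
                                 compartment_strength=common.COMPARTMENT_STRENGTH,
                                 seed=int(rng.integers(2**31)))
    io.write_contacts_coo(cm_ab, DATA / "contacts_ab.tsv")

    truth_tad = plant_truth(layout, block_bins=10**6, tad_bins=20)
    cm_tad = simulate_contact_map(layout, truth_tad, depth=common.DEPTH,
                                  tad_strength=common.TAD_STRENGTH,
                                  seed=int(rng.integers(2**31)))
    io.write_contacts_coo(cm_tad, DATA / "contacts_tad.tsv")

    truth_loop = plant_truth(layout, block_bins=10**6, tad_bins=10**6,
                             n_loops=250, loop_factor=common.LOOP_FACTOR,
                             loop_distance_bins=(15, 80),
                             seed=int(rng.integers(2**31)))
    cm_loop = simulate_contact_map(layout, truth_loop, depth=common.DEPTH,
                                   seed=int(rng.integers(2**31)))
    io.write_contacts_coo(cm_loop, DATA / "contacts_loops.tsv")

    (DATA / "truth_maps.json").write_text(json.dumps({
        "compartments": truth_ab.compartments.tolist(),
        "tad_boundaries": truth_tad.tad_boundaries.tolist(),
        "loops": truth_loop.loops.to_dict(orient="list"),
    }))

    # structure population + GAM + nuclear-position tracks
    layout_g = make_genome(common.GAM_CHROMS, common.BIN_SIZE)
    io.write_bin_table(layout_g, DATA / "bins_gam.tsv")
    truth_g = plant_truth(layout_g, block_bins=5, tad_bins=10)
    pop = simulate_structures(layout_g, NuclearGeometry.sphere(5000.0), truth_g,
                              n_structures=80, seed=int(rng.integers(2**31)))
    io.write_structures(pop, DATA / "population")
    seg = simulate_gam(pop, slice_thickness=1500.0, n_samples=400,
                       profiles_per_sample=2, seed=int(rng.integers(2**31)))
    io.write_segregation(seg, DATA / "gam_segregation.tsv")
    tracks = simulate_tracks(truth_g, pop, noise_sd=0.1,
                             seed=int(rng.integers(2**31)))
    io.write_bedgraph(layout_g, tracks["speckle"], DATA / "speckle.bedgraph")
    io.write_bedgraph(layout_g, tracks["lamina"], DATA / "lamina.bedgraph")
    (DATA / "truth_structures.json").write_text(json.dumps({
        "compartments": truth_g.compartments.tolist(),
    }))

    # loops with anchor-state signatures
    layout_l = make_genome([120_000_000, 80_000_000], common.BIN_SIZE)
    loops, segs, planted = simulate_loops_with_states(
        layout_l, n_clusters=4, loops_per_cluster=500,
        seed=int(rng.integers(2**31)))
    loops_out = loops.copy()
    loops_out["platform"] = "sim"
    loops_out["resolution"] = 10_000
    io.write_bedpe(loops_out, DATA / "loops.bedpe")
    io.write_bed(segs, DATA / "chromatin_states.bed",
                 cols=["chrom", "start", "end", "state"])
    np.savetxt(DATA / "loops_planted_cluster.txt", planted, fmt="%d")

    # expression
    tpm, breadth = simulate_expression(200, 12, housekeeping_frac=0.2,
                                       seed=int(rng.integers(2**31)))
    tpm.to_csv(DATA / "expression_tpm.tsv", sep="\t")
    np.savetxt(DATA / "expression_planted_breadth.txt", breadth, fmt="%d")

    print(f"wrote synthetic study inputs to {DATA}")
    print(f"  contact maps: 500 bins at {common.BIN_SIZE//1000} kb, depth {common.DEPTH:,}")
    print(f"  structures:   {pop.n_structures} diploid structures, {pop.n_beads} beads")
    print(f"  GAM:          {seg.n_samples} samples, mean detection "
          f"{seg.wdf().mean():.3f}")
    print(f"  loops:        {len(loops)} in 4 planted clusters")


if __name__ == "__main__":
    main()
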