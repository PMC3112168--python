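"""Generate the synthetic study inputs every downstream analysis consumes.

Writes, under results/data/:
  * two punctate-field images ("minus_piplc", "plus_piplc") rendered from
    identical generator settings — the null condition in which the cleavage
    treatment leaves puncta untouched — as 16-bit TIFFs with JSON ground truth;
  * an I-V dataset (10 cells/group) for the preset group pair (4-fold peak
    current enhancement, −13 mV half-activation shift) as tidy CSV;
  * a family of current traces (τ_act 2 ms, τ_inact 50 ms) as CSV;
  * a C-terminal sequence panel (intact motif, TM-replacement chimera tail,
    no motif) as FASTA;
  * paired gradient profiles (~20% raft signal; and a 90%→5% shifted pair)
    as CSV.
"""

import argparse
from pathlib import Path

from raftpuncta import io
from raftpuncta import synthetic_data as sd


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/data"))
    args = parser.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)
    seeds = sd.split_seed(args.seed, 10)

    # punctate fields: same generator settings before/after treatment
    for label, s in (("minus_piplc", seeds[0]), ("plus_piplc", seeds[1])):
        field = sd.generate_particle_field(200, min_separation=12.0, seed=s)
        img = sd.render_image(
            field, psf_sigma=0.8, background=100.0,
            poisson_noise=True, read_noise_sd=3.0, seed=s + 1,
        )
        io.write_image(img, out / f"puncta_{label}.tif", field=field)
        print(f"{label}: {field.n_total} particles, C_t = {field.c_total:.0f} px²")

    groups = sd.preset_alpha2delta_groups()
    records = sd.generate_iv_dataset(groups, n_cells=10, noise_sd=0.3, seed=seeds[2])
    io.write_iv_csv(records, out / "iv_dataset.csv")
    print(f"I-V dataset: {len(records)} cells over groups {sorted(groups)}")

    for i in range(5):
        trace = sd.generate_current_trace(
            tau_act=2.0, tau_inact=50.0, amplitude=-100.0,
            noise_sd=4.2, seed=seeds[3] + i,
        )
        io.write_trace_csv(trace, out / f"trace_{i:02d}.csv")
    print("current traces: 5 sweeps, 150 ms at 10 kHz")

    panel = [
        sd.generate_sequences("intact_gpi", seq_id="intact_motif", seed=seeds[4]),
        sd.generate_sequences("disrupted_tail", seq_id="tm_chimera", seed=seeds[4]),
        sd.generate_sequences("no_motif", seq_id="no_motif", seed=seeds[4]),
    ]
    io.write_fasta(panel, out / "cterm_panel.fasta")
    print(f"sequence panel: {[p.id for p in panel]}")

    peak = sd.generate_gradient_profile(raft_weight=0.2, noise_sd=0.0).signals.max()
    for label, w, s in (
        ("raft20_before", 0.2, seeds[5]),
        ("raft20_after", 0.19, seeds[6]),
        ("gpi_before", 0.9, seeds[7]),
        ("gpi_after", 0.05, seeds[8]),
    ):
        prof = sd.generate_gradient_profile(raft_weight=w, noise_sd=0.05 * peak, seed=s)
        io.write_gradient_csv(prof, out / f"gradient_{label}.csv")
    print("gradient profiles: raft20 pair (null) and gpi pair (shifted)")


if __name__ == "__main__":
    main()
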