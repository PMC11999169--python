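"""Generate the synthetic kinome-array study: two chip chemistries, two
groups (sedentary vs exercise), triplicate chips, planted IKK up-shift on
the STK chip plus planted dead/saturating spots on both.

Writes results/analysis/{stk,ptk}_reads.tsv, *_ground_truth.json and
*_kinase_map.gmt.
"""

from pathlib import Path

from kinopipe import krsa, simulate

OUT = Path("results/analysis")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for offset, chip in enumerate(("STK", "PTK")):
        layout = (simulate.ArrayLayout.stk() if chip == "STK"
                  else simulate.ArrayLayout.ptk())
        kmap = simulate.make_kinase_map(layout, seed=SEED)
        effects = {"IKK": 1.0} if chip == "STK" else {}
        cfg = simulate.SimulationConfig(
            layout=layout, kinase_map=kmap, planted_effects=effects,
            dead_peptide_frac=0.1, saturating_peptide_frac=0.1,
            noise_sd=2.0, seed=SEED + offset)
        reads, truth = simulate.simulate_arrays(cfg)
        simulate.write_reads(reads, OUT / f"{chip.lower()}_reads.tsv")
        truth.to_json(OUT / f"{chip.lower()}_ground_truth.json")
        krsa.write_gmt(kmap, OUT / f"{chip.lower()}_kinase_map.gmt")
        n_dead = len(truth.peptides_of_class("dead"))
        n_sat = len(truth.peptides_of_class("saturating"))
        print(f"{chip}: {layout.n_peptides} peptides "
              f"({layout.grid_rows}x{layout.grid_cols} grid), "
              f"{len(reads)} kinetic reads, planted {n_dead} dead + "
              f"{n_sat} saturating spots, effects {effects or 'none'}")


if __name__ == "__main__":
    main()
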