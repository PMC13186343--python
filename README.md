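# stickermd

Langevin dynamics of **sticker–spacer polymers** with strictly
single-valent, reversible sticker bonds — plus the graph-based cluster
analysis needed to study biomolecular condensates built from such chains.

Biomolecular condensates often form when phase separation couples to
percolation in multivalent macromolecules: *stickers* make transient,
specific crosslinks while *spacers* tune solubility and compaction.  A key
feature that generic isotropic attraction misses is that each sticker can
hold **at most one bond at a time**.  This single-occupancy bookkeeping
changes cluster statistics, slows coarsening, and can produce long-lived
multi-droplet states.  `stickermd` is a self-contained engine for this
model class, aimed at researchers who want time-resolved condensate
kinetics with valency-limited crosslinking, reproducible to the bit given
a pair of seeds.

## Model

Chains are linear bead polymers built from a repeated sticker/spacer block
template.  The force field (real units: Å, fs, kcal/mol, g/mol, K):

- backbone bonds: `E = Kb (R − R0)²` with `Kb = 3 kcal/mol/Å²`, `R0 = 10 Å`;
- bending: `E = κ (1 − cos θ)` with `κ = 2 kcal/mol`, `θ` the deviation
  from a straight chain;
- non-specific cohesion: Lennard-Jones `E = 4 Ens [(σ/r)¹² − (σ/r)⁶]`,
  `σ = 10 Å`, truncated (unshifted) at `Rmax = 2.5 σ`, excluded only for
  directly bonded pairs;
- specific sticker bonds: a shifted harmonic well
  `E = Es/(R0ₛ−Rcut)² [(R−R0ₛ)² − (Rcut−R0ₛ)²]` for `R < Rcut`, zero
  beyond, with `R0ₛ = 1.122 σ` and `Rcut = R0ₛ + 1.5 Å`; the well depth at
  `R0ₛ` is `−Es`.

Dynamics is underdamped Langevin (BAOAB splitting of velocity Verlet plus
an exact Ornstein–Uhlenbeck velocity refresh with damping time `t_damp`).
Once every 20 steps a stochastic bond pass runs: bonded sticker pairs with
`R ≥ Rcut` break with probability `p_off`; unpaired complementary pairs
within `Rcut` are visited in random order and bond with probability `p_on`
(defaults `p_on = p_off = 1`), respecting valency 1.  Complementarity is
heterotypic by default (A binds B; A–A and B–B do not).

Cluster statistics use the chain graph (one node per chain, one edge per
inter-chain sticker bond).  The **average cluster occupancy**

&nbsp;&nbsp;&nbsp;&nbsp;ACO = Σᵢ fᵢ Sᵢ = (1/N) Σᵢ nᵢ Sᵢ², with fᵢ = nᵢ Sᵢ / N,

is the size-weighted mean cluster size; normalized by the chain count N it
runs from 1/N (fully dispersed) to 1 (a single percolated cluster).

## Worked example

Forty 50-bead chains (10 stickers each, two complementary types) in a
300 Å box, Es = 6 kT and Ens = 0.3 kT at 310 K:

```python
import stickermd as sm

template_a, template_b = sm.two_component_templates()   # 50 beads, 10 stickers
state, topology = sm.pack_system(
    [(sm.build_chain(template_a), 20), (sm.build_chain(template_b), 20)],
    box=(300.0, 300.0, 300.0), seed=1,
)
params = sm.ForceFieldParams.from_kT(es_kT=6.0, ens_kT=0.3)
config = sm.SimulationConfig(n_steps=50_000, thermo_every=10_000,
                             seed_thermostat=1, seed_bonds=2)
state.velocities = sm.init_velocities(config.T, config.mass, seed=3, n=state.n_beads)
result = sm.run(state, topology, params, config)

print(result.thermo[["step", "E_bond", "E_pair", "E_potential", "bonded_fraction"]]
      .to_string(index=False))
stats = sm.cluster_components(state, topology)
print(f"saturation = {sm.sticker_saturation(state, topology):.3f}, "
      f"normalized ACO = {stats.aco_normalized:.3f}, "
      f"largest cluster = {int(stats.sizes.max())} chains")
```

prints

```
 step       E_bond      E_pair  E_potential  bonded_fraction
    0 5.449861e-25   52.965150  3036.335416            0.000
10000 4.938323e+02 -196.764341  1682.948230            0.150
20000 4.435447e+02 -193.298177  1589.496008            0.200
30000 4.399196e+02 -195.365482  1589.407365            0.240
40000 3.949233e+02 -187.805036  1502.286403            0.295
50000 3.917504e+02 -203.410472  1503.819791            0.330
saturation = 0.330, normalized ACO = 0.857, largest cluster = 37 chains
```

Reversible bonds form (the bonded fraction climbs as each bond lowers
`E_bond` by Es), the Lennard-Jones term follows as chains pack together,
and by 50 000 steps 37 of the 40 chains are crosslinked into one network
(normalized ACO 0.86) while two thirds of the stickers are still free —
clustering runs ahead of sticker saturation.

The same pipeline is scriptable from the shell:

```bash
stickermd build --config demo.toml --out-dir out/
stickermd run --config demo.toml --data out/system.data --out-dir out/
stickermd analyze --what aco out/final.data --out-dir out/
stickermd validate-db --es 2,3,4,5,6,7 --frames 1e6 --seed 1 --out-dir out/
stickermd titrate --es-grid 1,3,5,7 --seed 1 --out-dir out/
```

Every command writes a JSON manifest (config snapshot, seeds, version,
output inventory) from which the result can be reproduced exactly.

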