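# tumorpotts

A multi-cell virtual-tissue simulator of tumor growth and somatic
evolution, built on the Glazier–Graner–Hogeweg (GGH / Cellular Potts)
model.  It is written for computational-oncology and tissue-modeling
researchers who want a self-contained, reproducible Python implementation
of the classic "evolution of reduced cohesion" tumor model: cells on a
2D lattice move by Metropolis voxel-copy dynamics under adhesion, volume
and surface constraints; a steady-state glucose field drives growth,
quiescence, starvation and necrosis; and heritable Gaussian mutation of
adhesion-molecule levels at each division lets the tumor's cohesivity
evolve under the selection pressure created by its own emergent
stratification.

## Model in brief

Effective energy over lattice configurations σ:

    H = Σ_{x,y neighbors} −b(σ(x), σ(y)) · [σ(x) ≠ σ(y)]
        + Σ_c λ_vol (v_c − V_c)² + Σ_c λ_sur (s_c − S_c)²

    b(i, j) = Σ_{m,n} k_{m,n} min(N_m^i, N_n^j)        (adhesion binding)

Voxel-copy attempts are accepted with probability 1 for ΔH ≤ 0 and
exp(−ΔH/T_m) otherwise; one MCS (= 6 simulated minutes) is one attempt
per lattice voxel.  Glucose obeys a steady-state reaction–diffusion
equation with Michaelis–Menten tumor uptake; cells accumulate starvation
damage below 0.032 fmol/voxel (0.5 mM) and health above it, switching
between proliferating, quiescent and necrotic states at fixed thresholds.
Cells past their doubling volume split at a random orientation;
non-stem lineages senesce after ~N(8, 2) divisions; stem divisions yield
a stem daughter with probability 0.2; cadherin and integrin levels mutate
with probability 0.1 by N(level, 2) draws rejected outside [0, 16].  The
cell–Medium surface tension γ = b(cell,cell)/2 − b(cell,Medium)
diagnoses cohesion: the reference configuration starts at γ = 6.4 and
evolution drives it toward the invasive regime γ < 0.

See `docs/methods.md` for the full model description, parameter table
semantics, numerical choices and known limitations.

## Worked example

Run a small replica (50×50 lattice, 2000 MCS ≈ 8.3 simulated days) and
census the result:

```python
>>> from tumorpotts import make_scaled_config, run, populations_by_type, \
...     mean_surface_tension, AdhesionModel
>>> cfg = make_scaled_config("smoke", steps=2000, snapshot_interval=500)
>>> series, sim = run(cfg, seed=1)
>>> last = series[series.mcs == 2000]
>>> populations_by_type(last)
{'PCancer': 1, 'QCancer': 0, 'Necrotic': 0, 'PStem': 1, 'QStem': 0}
>>> round(mean_surface_tension(last, AdhesionModel()), 2)
6.4
```

The seeded quiescent stem cell accumulated health in the glucose-rich
stroma (~0.11 per MCS against the 79.5 threshold), switched to the
proliferating state around MCS 800, grew to its doubling volume and
divided once: by MCS 2000 the tumor is a proliferating stem cell plus a
cancer daughter.  The mean surface tension is still the cohesive initial
6.4 — the single division left the adhesion levels unmutated (each
molecule mutates with probability 0.1 per division).  Longer desk-scale
runs (`make_scaled_config("desk")`,
100×100) show the full early sequence: growth to the supply-limited
tumor size, quiescence cycling, senescence-driven necrosis inside the
cluster, and slow evolution of cadherin levels.

The same things are available from a shell:

```sh
tumorpotts simulate --profile desk --seed 1 --out runs/desk1
tumorpotts analyze clusters runs/desk1/snapshots.csv
tumorpotts analyze tension runs/desk1/snapshots.csv
tumorpotts scan --profile desk --pm 0.1,0.3 --dam 0.5,2.0 --replicas 3 --out runs/scan
```

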