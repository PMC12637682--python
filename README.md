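# ionflux

Ion-channel conduction analysis for computational electrophysiology and
single-channel recordings.

Whether a channel structure represents the physiologic open state cannot be
read off a static model: the structure has to conduct, and conduct at the
right rate, with the right current–voltage shape, through the right route.
`ionflux` implements the analysis chain used to make that call for
pentameric ligand-gated ion channels (pLGICs):

* **permeation counting** — detect complete crossings of the transmembrane
  gate in an ion trajectory with an exhaustively validated state machine,
  robust to periodic boundaries and partial entries;
* **computational electrophysiology** — fixed-field currents
  I = z·e·(N_out − N_in)/T at ΔV_m = E_z·L_z, per-polarity slope
  conductances γ_o and γ_i by OLS over replicates, and the rectification
  ratio γ_o/γ_i (1 = Ohmic, >1 = outward rectification);
* **conduction pathway decomposition** — classify each conducted ion as
  entering the extracellular vestibule through the apical (axial) aperture
  or a lateral intersubunit fenestration, with per-fenestration counts,
  vestibule-return diagnostics, and bulk-normalized ion number-density
  profiles;
* **pore geometry** — maximal-sphere radius profiles along the pore axis or
  any curved path (fenestrations), static or per-frame, via a deterministic
  multi-start search checked against a dense grid oracle;
* **free-energy surfaces** — 2D adaptive-biasing-force estimation
  (0.1×0.1 Å² bins, 250-sample ramp) with window restraints, convergence
  diagnostics (PMF RMSD, sampling entropy/heterogeneity), window stitching,
  and string-method minimum free-energy pathways with fixed endpoints;
* **single-channel electrophysiology** — all-points histograms,
  two-Gaussian fits for the single-channel current, per-polarity slope
  conductances, paired t-tests, and one-way ANOVA with Monte Carlo
  Dunnett many-to-one comparisons.

A synthetic-data engine (`ionflux.synthdata`) generates every input with
known ground truth — Brownian ions in an idealized channel under an applied
field, scripted crossings, two-state 20 kHz patch traces, and atom clouds
with analytic pore profiles — so the whole chain is testable end to end.
`ionflux.reference` holds deliberately slow brute-force oracles used only
for cross-checks.

## Worked example

Recover the conductance of a synthetic Ohmic channel from a fixed-field
campaign (ΔV_m ∈ {−250, −100, 0, +100, +250} mV, three replicates each),
then a single-channel current from a synthetic patch trace:

```python
from ionflux.io_core import ChannelGeometry
from ionflux.permeation import fit_conductance, iv_from_trajectories
from ionflux.synthdata import PatchSpec, markov_patch_trace, ohmic_campaign
from ionflux.ephys import single_channel_current

geom = ChannelGeometry()
entries, gamma_true = [], None
for v, rep, traj, truth in ohmic_campaign(duration=50.0, seed=1, save_every=4):
    entries.append((v, rep, traj))
    gamma_true = truth.programmed_gamma_pS

fit = fit_conductance(iv_from_trajectories(entries, geom))
print(f"programmed gamma : {gamma_true:6.1f} pS")
print(f"fitted gamma_o   : {fit.gamma_o:6.1f} +/- {fit.se_o:.1f} pS")
print(f"fitted gamma_i   : {fit.gamma_i:6.1f} +/- {fit.se_i:.1f} pS")
print(f"rectification    : {fit.ratio:6.2f}")

rec, truth = markov_patch_trace(PatchSpec(gamma_pS=90.0, seed=1), holding_mV=-100.0)
i = single_channel_current(rec)
print(f"single-channel current at -100 mV: {i:+.2f} pA "
      f"(true {truth['i_true_pA']:+.2f} pA)")
```

Output:

```
programmed gamma :  387.3 pS
fitted gamma_o   :  364.8 +/- 29.2 pS
fitted gamma_i   :  353.6 +/- 16.7 pS
rectification    :   1.03
single-channel current at -100 mV: -8.99 pA (true -9.00 pA)
```

Both fitted slopes sit within one to two standard errors of the programmed
387.3 pS (the closed-form conductance of the uniform tube at these
parameters — 15 × 50 ns is a deliberately small campaign), and the
rectification ratio is 1 within noise, as it must be for an Ohmic channel.
The patch pipeline recovers the programmed 9 pA open-level separation to
0.1%.

A thin CLI exposes the same stages as `ionflux synth|perm|pore|pmf|ephys`
subcommands operating on CSV/JSON/PDB files; run `ionflux --help`.

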