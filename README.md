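# sumonmr

Analysis toolkit for solution-NMR characterisation of SUMO-family
proteins: chemical-shift-perturbation (CSP) titrations with dissociation
constant fitting, backbone ¹⁵N relaxation (T1/T2/hetNOE), structural
ensemble statistics, NOE distance-restraint bookkeeping, and
SUMO-specific sequence-motif scanning — plus seeded synthetic-data
generators so every analysis can be validated by parameter recovery.

## Who this is for

Groups studying SUMO/ubiquitin-like modifiers (or any small protein
binding a short peptide in fast exchange) who want the quantitative
post-processing after spectra have been processed and assigned: peak
lists in, binding constants, interface maps, flexibility profiles and
ensemble statistics out.

## The models

**CSP and binding.** A ligand titrated into a ¹⁵N-labelled protein in
fast exchange moves each amide cross-peak by the bound fraction of the
protein. The weighted CSP per residue is

    CSP = √[(δH_free − δH_bound)² + ((δN_free − δN_bound)/5)²]

and the observed CSP at total concentrations [P]t, [L]t follows the
exact 1:1 quadratic isotherm

    CSP_obs = CSP_max · {([P]t+[L]t+Kd) − √[([P]t+[L]t+Kd)² − 4[P]t[L]t]} / 2[P]t

The binding interface is called as residues with CSP above
mean + 2·SD (computed over non-broadened residues; peaks that
exchange-broaden out of the spectra are reported separately). The Kd is
fit globally across residues — one shared Kd, one CSP_max per residue —
with bootstrap uncertainties over titration points.

**Relaxation.** T1 and T2 come from per-residue mono-exponential fits
I(t) = I0·e^(−t/T) over the delay grids; hetNOE is I_sat/I_unsat with
propagated error. hetNOE ≤ 0 marks highly flexible residues (disordered
termini), ≥ 0.5 the rigid β-grasp core.

**Ensembles.** Multi-model structures are iteratively superposed to
their mean (Kabsch); precision is reported as mean (±SD)(min..max)
per-model RMSD-to-mean over a residue range and atom class, with
per-residue RMSF for local flexibility. NOE restraints are classed by
sequence separation |i−j|: short ≤ 1, medium 2–4, long ≥ 5.

**Motifs.** ψKXE SUMOylation-consensus scanning (ψ ∈ {L,I,V}), a
versioned SIM (SUMO-interacting motif) heuristic — branched-hydrophobic
4-mer core with acidic/serine flanks — global BLOSUM62 alignment with
percent identity, and K→R construct generation.

## Worked example

```python
import sumonmr as s
from sumonmr.synthetic import default_interface

design = s.TitrationDesign(
    true_kd=31.0, noise_sd=0.005,
    interface_residues=default_interface(seed=42), seed=42,
)
series = s.gen_titration(design)
records = s.csp_profile(series, len(series.points) - 1)
call = s.call_interface(records)
print(f"interface threshold: {call.threshold:.4f} ppm")
print(f"interface residues:  {sorted(call.interface_residues)}")
fit = s.fit_kd(series, n_bootstrap=500, seed=0)
print(f"Kd = {fit.kd:.1f} uM (bootstrap SE {fit.kd_stderr:.1f}, "
      f"95% CI {fit.kd_ci95[0]:.1f}-{fit.kd_ci95[1]:.1f})")
```

prints

```
interface threshold: 0.2071 ppm
interface residues:  [21, 22, 31, 39]
Kd = 30.2 uM (bootstrap SE 3.7, 95% CI 29.2-57.8)
```

A synthetic titration was generated with a true Kd of 31 µM and
0.005 ppm peak-position noise; the mean+2·SD rule finds the planted
interface residues with the largest maximal shifts, and the global fit
recovers the dissociation constant with its 95% interval covering the
truth.

The same pipeline runs from the shell:

```
sumonmr simulate --seed 42 --out run/
sumonmr csp     --out run/ --manifest run/titration/manifest.csv
sumonmr fitkd   --out run/ --manifest run/titration/manifest.csv
sumonmr all     --seed 42 --out run/    # everything end to end
```

Every stage writes CSV/text reports plus a JSON summary embedding the
exact configuration used.

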