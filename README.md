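# dimerscope

Prediction and characterization of **weak-affinity protein homodimers** —
the kind of transient, millimolar-Kd complexes (such as membrane-anchored
small-GTPase dimers) that are too unstable to capture in solution and too
small to resolve in cells. The package implements, as a tested reusable
library with a CLI, the complete computational workflow around such a
system:

* **docked-pose clustering and viability filtering** — greedy-leader
  clustering of rigid docking poses by interface Cα RMSD, a 5% cluster
  enrichment rule, and three empirical filters (the interface must involve
  reactive/co-evolving residues and not be loop-only; the effector-binding
  loop of each protomer must stay solvent exposed; both C-terminal lipid
  anchors must be able to insert into one membrane);
* **residue coevolution hotspot mapping** — mutual information with
  average-product correction (MI−APC) over a multiple sequence alignment,
  z-standardised so a single score cutoff (default > 2.0) is meaningful,
  gated by solvent exposure;
* **quantitative interface metrics** — buried surface area
  ΔSASA = SASA(A) + SASA(B) − SASA(AB) by Shrake–Rupley with a 0.14 nm
  probe, hydrogen bonds (0.3 nm donor–acceptor / 20° angle), hydrophobic
  carbon–carbon contacts (0.38 nm), inter-monomer centre-of-mass distance
  d_COM, relative monomer orientation δ, salt bridges, π-stacks and a
  quasi-symmetry score;
* **binding thermodynamics from a potential of mean force** — a mean-force
  profile F(r) along d_COM is integrated to W(r) with full error
  propagation, and the standard-state dissociation constant follows from
  the radial configurational integral
  `Ka = C° ∫ 4πr² exp(−W(r)/RT) dr`, `Kd = 1/Ka`,
  `ΔG_bind = RT ln(Kd / 1 M)`;
* **computational alanine scanning** — side-chain truncation plus a
  transparent pairwise Coulomb (ε = 4r) + Lennard-Jones interaction energy,
  ranking interfacial residues by ΔΔE;
* **Ripley's K nanocluster statistics** — edge-corrected K(r) and
  L(r) − r for 2-D point patterns (immunogold EM coordinates), n-weighted
  mean curves, and a permutation bootstrap test on max L(r) − r;
* **synthetic-data generators** with exact ground truth (planted salt
  bridges, covarying alignment columns, Gaussian-well PMFs of known Kd,
  planted pose clusters, Thomas/CSR point processes) so the whole pipeline
  is testable without any external data.

All lengths are in nm, energies in kcal/mol, areas in nm².

## Worked example

Generate a synthetic helix homodimer with planted interactions and
characterise its interface:

```bash
$ dimerscope synth dimer --seed 0 --out-dir demo
$ dimerscope interface demo/dimer.pdb --n-points 960
{
 "hb_count": 0,
 "hc_count": 2,
 "d_com_nm": 1.1923,
 "delta_sasa_nm2": 3.472,
 "quasi_symmetry": 0.0667,
 "salt_bridges": [
  ["('A', 101, 'LYS')", "('B', 107, 'GLU')", "0.3199"],
  ["('B', 97, 'ARG')", "('A', 98, 'GLU')", "0.3200"]
 ],
 "pi_stacks": [
  ["('A', 94, 'HIS')", "('B', 95, 'HIS')", "0.4000", "0.017", "parallel"]
 ]
}
```

The two planted salt bridges (Lys101–Glu107 and Arg97–Glu98, planted at
0.32 nm) and the His94–His95 parallel stack (0.40 nm centroids) are
recovered exactly; the dimer buries 3.47 nm² and its centres of mass sit
1.19 nm apart — the planned separation of 1.2 nm.

Integrate a mean-force profile into a PMF and a standard-state Kd:

```bash
$ dimerscope synth meanforce --seed 0 --out-dir demo
$ dimerscope pmf demo/mean_force.tsv
{
 "kd_molar": 0.00010225510990120178,
 "dg_bind_kcal_mol": -5.478,
 "minima_nm": [[3.6, 3.497]],
 "bound_window_nm": [2.6, 4.071]
}
```

The default synthetic well (3.5 kcal/mol deep at 3.6 nm) gives a single
PMF minimum at 3.6 nm and Kd ≈ 0.10 mM (ΔG_bind ≈ −5.5 kcal/mol); the
generator's sidecar `demo/ground_truth.json` records the analytic Kd
(1.018 × 10⁻⁴ M) for comparison. For scale: a Kd of 5 mM corresponds to
ΔG_bind ≈ −3.2 kcal/mol at 300 K and 107 mM to −1.3 kcal/mol, a ~21-fold
affinity difference.

The full pipeline (cluster → filter → characterize → alanine scan →
thermodynamics) runs from a YAML config:

```bash
dimerscope synth poses --seed 3 --out-dir bundle
dimerscope synth meanforce --seed 3 --out-dir bundle
dimerscope run config.yaml     # see RunConfig for the threshold defaults
```

On the bundled six-cluster docking scenario this reports
`"n_survivors": 4`: six major clusters pass the 5% enrichment rule, one is
removed because its lipid anchors point to opposite faces and one because
its interface is loop-only.

The library mirrors every subcommand (`dimerscope.cluster_poses`,
`dimerscope.kd_from_pmf`, `dimerscope.ripleys_k`, ...); selections use a
small expression language, e.g.
`structure.select("chain A and resid 87-104 and name CA")`.

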