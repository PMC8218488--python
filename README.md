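# castelo

Rank the submolecular moieties ("atom subtypes") of a bound lead molecule by
how much they destabilize target–lead binding, from a molecular-dynamics
trajectory of the complex — and convert follow-up binding free-energy
changes into predicted potency fold-changes.

**Who it is for.** Computational chemists doing lead optimization who have a
trajectory of a stably bound lead and want data-driven modification
hotspots, without structure–activity data.

## Method in brief

Each trajectory frame is featurized as a binary contact matrix C ∈ {0,1}^(N×M)
between ligand and protein atoms (cutoff 4.5 Å), enriched with a temporal
channel |C(t) − C(t−δ)| — the *dynamism tensor*. Ligand atoms are grouped
into subtypes by Lennard-Jones similarity (ε and Rmin/2 within 10 %,
transitively closed). Per subtype, an ensemble of six convolutional
variational autoencoders (f ∈ {32,64} filters × d ∈ {3,5,10} latent
dimensions; four 1×7 stride-2 conv layers; BCE + KL loss, RMSProp) embeds
the frames, HDBSCAN (min cluster size 50) clusters the embeddings, and the
per-frame cluster-size series C_{t,A} is compared against the
whole-molecule RMSD reference clustering C_{t,S} (quality-threshold, 2.0 Å)
by

    CosSim  = Σ_t C_{t,A}·C_{t,S} / (√Σ_t C²_{t,A} · √Σ_t C²_{t,S})
    AvgDiff = Σ_t (C_{t,A} − C_{t,S}) / T

Mean-centred over subtypes (nCosSim, nAvgDiff) and averaged over the
ensemble, these rank the subtypes; the lowest-ranked ("malicious") subtype
is the modification candidate — valid when the reference binding mode is
stable (largest cluster > 50 ns). Suggested modifications can be verified by
alchemical free-energy calculations; the package converts those results via

    CRS = exp(−(ΔΔF − ΔΔF_ref)/RT)

into relative potency (for the built-in sweetener benchmark: computed
relative sweetness vs sucrose).

See `docs/methods.md` for the full model description and design choices.

## Worked example

Generate a synthetic bound-complex contact system with a planted unstable
subtype and rank the subtypes:

```python
from castelo import (SyntheticSpec, generate_contact_system,
                     analyze_contact_system, CVAEConfig)

system = generate_contact_system(SyntheticSpec(seed=1))   # T=1000, M=128
report = analyze_contact_system(
    system.contacts, system.atom_to_subtype, system.reference,
    delta=25, filters=(32,), latent_dims=(3, 5), base_seed=1,
    cvae_config=CVAEConfig(max_epochs=12, patience=3, batch_size=125),
)
print(report["ranking"][["subtype_id", "n_cos_sim", "n_avg_diff", "rank"]])
print("planted malicious subtype:", system.malicious_subtypes)
```

Output:

```
   subtype_id  n_cos_sim  n_avg_diff  rank
0           4  -0.010845     -407.46     1
1           0  -0.001024       92.19     2
2           1  -0.001024       92.19     3
3           2   0.006447      111.54     4
4           3   0.006447      111.54     5
planted malicious subtype: [4]
```

Subtype 4 — the planted high-churn block whose contacts never settle —
ranks 1 (most malicious): its clustering departs most from the
whole-molecule reference (negative nCosSim, strongly negative nAvgDiff,
i.e. its frames sit in far smaller clusters than the molecule's binding
modes). The stable subtypes sit above it with near-zero centred metrics.

The free-energy calculator reproduces the published sweetener table:

```sh
$ castelo crs
         name    ddF  ddF_err  log_rs  log_crs  log_crs_err
      sucrose  -6.90     0.70    0.00    -0.00         0.70
4R-Cl-sucrose -10.20     0.80    0.70     2.33         0.75
    sucralose -11.70     0.80    2.78     3.38         0.75
       dulcin -10.60     0.40    2.40     2.61         0.57
  isovanillyl -11.10     0.80    2.60     2.96         0.75
```

On real data, `castelo run topology.psf trajectory.dcd --ligand "resname
LIG" --params ffnonbonded.prm` executes the same pipeline end-to-end
(contact computation, subtyping from the force-field parameter file, CVAE
ensemble, clustering, ranking) and writes `report.json`, `ranking.csv` and
intermediate artifacts; `castelo --help` lists the stage-by-stage
subcommands (`contacts`, `subtypes`, `embed`, `cluster`, `rmsd-cluster`,
`rank`, `crs`, `synth`).

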