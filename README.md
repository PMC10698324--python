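# boltzmap

Which new molecular structures are likely to appear through random mutations?
`boltzmap` answers this question for two classic genotype–phenotype (GP) map
models — HP lattice proteins on compact W×H lattices and RNA secondary
structures — by comparing two predictors of the **phenotypic mutation
probability** φ<sub>qp</sub>, the probability that a single-site substitution
applied to a sequence folding into structure *p* yields structure *q*:

* the **phenotypic frequency** f<sub>q</sub> — the fraction of all sequences
  whose unique minimum-free-energy (mfe) structure is *q*; and
* the **neutral-set Boltzmann average** p<sub>qp</sub> — the Boltzmann
  frequency of *q*, F<sub>q</sub> = exp(−G<sub>q</sub>/k<sub>B</sub>T) / Σ<sub>r</sub> exp(−G<sub>r</sub>/k<sub>B</sub>T),
  averaged over all sequences that fold into *p*.

The second predictor extends the idea of *plastogenetic congruence* — that a
sequence's high-frequency suboptimal structures foreshadow its mutational
structure changes — from individual sequences to whole neutral sets.  The
package provides exact enumeration machinery for the HP model (every compact
structure and every one of the 2<sup>L</sup> sequences), a pluggable
folding-engine contract for RNA, seeded neutral-set samplers, and the
ranking/correlation metrics used to score the two hypotheses.

It is aimed at researchers studying evolvability, neutral networks and the
arrival of phenotypic variation, and at anyone who needs a clean, exactly
tested HP-lattice GP map.

## What is inside

| module | contents |
| --- | --- |
| `boltzmap.lattice` | compact self-avoiding walk enumeration, symmetry reduction (reversal-distinct by default), contact sets |
| `boltzmap.hp_thermo` | HP contact energies, full-catalogue Boltzmann ensembles, unique-mfe assignment (ties → UNFOLDED) |
| `boltzmap.gpmap` | exact sequence→structure tables, neutral sets, f<sub>q</sub>, φ rows |
| `boltzmap.boltzmann_stats` | p<sub>qp</sub> and p<sub>q</sub>, exact or by seeded sampling; ground-state occupancy statistics |
| `boltzmap.compare` | top-k capture and log–log Pearson scoring of the two predictors |
| `boltzmap.rna` | folding-engine contract, 0.02 kcal/mol uniqueness window, truncated ensembles from suboptimal lists, dot-bracket utilities, mock + ViennaRNA engines |
| `boltzmap.neutral` | site-scanning neutral-set walks (with optional basepair swaps for RNA) |
| `boltzmap.synthetic` | additive random-field toy landscapes, mock engines, small-lattice suite |
| `boltzmap.io` / `boltzmap.cli` | TSV/NPY formats, run configs, `boltzmap` command-line tool |

## Worked example

Score both predictors on the complete 4×4 lattice (L = 16, all 65 536
sequences, 69 reversal-distinct compact structures) at the default reduced
temperature k<sub>B</sub>T = 0.5:

```sh
$ boltzmap compare --lattice 4 4 --out out44
n_structures: 69
mean_capture_fq: 15.4493
mean_capture_pqp: 17.7391
mean_pearson_fq: 0.3418
mean_pearson_pqp: 0.4719
```

For each of the 69 initial structures *p*, the 30 outcomes with the highest
exact φ<sub>qp</sub> are compared with each predictor's own top 30: the
Boltzmann average p<sub>qp</sub> captures on average 17.7 of the 30 most
likely structural changes, against 15.4 for the phenotypic frequency, and its
log–log Pearson correlation with φ<sub>qp</sub> is higher as well (0.47 vs
0.34) — likely mutational changes track high-Boltzmann-frequency suboptimal
structures more closely than they track global structure abundance.

The same library calls work from Python:

```python
from boltzmap import build_catalogue, build_full_gpmap, compare_all, summarize

cat = build_catalogue(4, 4)          # 69 compact structures
gp = build_full_gpmap(cat)           # exact mfe assignment of 2^16 sequences
summarize(compare_all(gp, cat, kBT=0.5, k=30))
```

On the full 5×5 lattice (L = 25) the same machinery enumerates all 2<sup>25</sup>
sequences in well under a minute; all 1081 reversal-distinct compact
structures turn out to have nonempty neutral sets.  Ground-state occupancy
shows the temperature extremes of the model: a typical folding sequence keeps
>99.9% of its Boltzmann ensemble in the ground state at k<sub>B</sub>T = 0.1
but only ~3% at k<sub>B</sub>T = 1.

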