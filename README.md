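# tmclass

Not every transmembrane (TM) helix carries evolutionary signal.  Many are
*simple* hydrophobic anchors: runs of aliphatic residues that look alike
across unrelated proteins because the lipid bilayer demands it, not because
the proteins share ancestry.  Others are *complex*: they carry charged
(R/D/E/H), structural (G/P) and aromatic (F/W) residues on a hydrophobic
background and participate in catalysis, ligand binding or helix–helix
packing — these do carry homology information.  Simple helices are a classic
source of spurious hits in sequence-similarity searches; complex helices are
worth keeping in domain models.

`tmclass` classifies annotated TM helices as **simple**, **complex** or
**twilight** (undecidable), and can mask the simple ones with runs of `X`
before a homology search, the way low-complexity filters mask compositionally
biased regions.  It is aimed at annotation-pipeline builders and anyone
curating TM-containing domain models.

## The score

Each helix is reduced to two windowed sequence measures:

- **Hydrophobicity** `x_φ` — every length-19 window is scored as the sum of
  per-residue sign-reversed octanol-minus-interface transfer free energies
  (Wimley–White whole-residue scales), and the helix value is the mean over
  windows (kcal/mol).  High values mean high membrane-insertion propensity.
- **Complexity** `x_c` — every length-12 window is scored as the Shannon
  entropy (bits) of its residue composition with I, V and L pooled into one
  group (so shuffling aliphatics does not create apparent complexity), again
  averaged over windows.

Against reference statistics (μ_φ, σ_φ, μ_c, σ_c, ρ) of functional TM
helices, the pair is normalized, x̃ = (x − μ)/σ, and collapsed into a signed
univariate score

```
z = (−1)^s · (x̃_φ² + x̃_c²),    s = 1  iff  x̃_φ ≥ −(1/ρ)·x̃_c
```

i.e. the squared distance from the reference centroid, negative on the
high-hydrophobicity/low-complexity side of the normal to the
complexity–hydrophobicity regression line.  Substituting the diagonal point
(μ_c − fσ_c, μ_φ + fσ_φ) gives the analytic threshold family
`z_threshold = −2f²`: f = 1.282 (10 % one-tailed rate) gives −3.29 and
f = 1.645 gives −5.41.  The default twilight zone is `[−5.41, −3.29]`:
helices below it are simple, above it complex, inside it unclassified.

Default reference constants are the published functional-TM values
μ_φ = 0.64, σ_φ = 2.85, μ_c = 2.40, σ_c = 0.30, ρ = −0.436; alternatively
they can be re-estimated from any segment set (`fit(ref=None)` or the
`derive-stats` subcommand).

## Worked example

```
$ cat demo.fasta
>HAMP_TM example single-TM helix
MKVSLLLVLLIALLLALLLALLLGQRDE
>PIGP_TM1 first helix of a two-TM protein
MAGFVLYILSQLAFILYLLWAFVPE
$ cat demo.tsv
HAMP_TM	5	23
PIGP_TM1	3	22
$ tmclass classify demo.fasta demo.tsv --out report.tsv
TM complexity classification
============================================================
segments: 2   hydro window: 19   complexity window: 12   IVL grouped: True
reference: mu_phi=0.64 sigma_phi=2.85 mu_c=2.40 sigma_c=0.30 rho=-0.436
twilight zone: [-5.41, -3.29]
classes: 1 simple / 1 twilight / 0 complex
------------------------------------------------------------
protein_id  start  end  x_c  x_phi      z  s    class
   HAMP_TM      5   23 0.73  10.01 -41.77  1   simple
  PIGP_TM1      3   22 2.19   5.77  -3.71  1 twilight
```

The HAMP anchor helix (`LLLVLLIALLLALLLALLL`) has near-zero complexity
(0.73 bits; pure I/V/L would be 0) and very high insertion propensity
(10.01 kcal/mol), hence a deeply negative z — a textbook simple helix that
would light up spurious hits in a search.  The first PIG-P helix lands in
the twilight zone: hydrophobic, but compositionally rich enough that
classification is withheld.  `tmclass mask demo.fasta demo.tsv --out
masked.fasta --f 1.282` would replace only the HAMP helix with `X`s.

The same pipeline is available as a library:

```python
from tmclass import TMComplexityModel, TMSegment

model = TMComplexityModel([TMSegment("HAMP_TM", 5, 23, "LLLVLLIALLLALLLALLL")])
results = model.fit()          # published reference constants, default zone
print(results.summary())
results.to_frame()             # pandas DataFrame with x_c, x_phi, z, class
```

`tmclass.synthetic_fixtures` generates seeded anchor-like/functional-like
proteins, measure clouds and hit tables, so the whole pipeline — including
masked-search evaluation (`tmclass search-eval`) and enrichment statistics
(`tmclass enrich`) — runs without any external data.

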