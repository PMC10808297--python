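# microfoodweb

Analysis toolkit for **soil micro-food webs** — the consumer–resource
network of bacteria, fungi and nematodes that routes carbon and nutrients
through decomposition channels in soil. Given genus-level sample × taxon
count tables for the three kingdoms (plus a nematode trait table), the
package computes the standard descriptors ecologists use to read food-web
condition from nematode communities, and infers thresholded cross-kingdom
co-occurrence networks. A synthetic-community generator with plantable
structure makes every stage testable without sequencing data.

Intended users: soil ecologists and microbiome analysts working with
amplicon-derived community tables (16S/ITS/18S) who want the nematode
faunal-analysis toolchain in scriptable, tested Python rather than
spreadsheets.

## What it computes

**Alpha diversity** — observed richness, Chao1
`S_chao1 = S_obs + n₁(n₁−1)/(2(n₂+1))`, and Shannon
`H = −Σ (nᵢ/N) ln(nᵢ/N)`.

**Faunal indices** (Ferris guild-weighted framework; weights are
configurable). With enrichment component `e = 3.2·Ba1 + 0.8·Fu2`, basal
`b = 0.8·(Ba2 + Fu2)` and structure `s = Σ_{cp 3–5} w(cp)·N`
(`w = 1.8, 3.2, 5.0`):

    EI = 100·e/(e+b)    SI = 100·s/(s+b)    BI = 100·b/(e+s+b)
    CI = 100·0.8·Fu2 / (3.2·Ba1 + 0.8·Fu2)

plus maturity indices MI and PPI (abundance-weighted mean c-p of
free-living and plant-parasitic taxa), PPI/MI, trophic diversity
TD = 1/Σpᵢ², and the A–D faunal-profile quadrant of the (EI, SI) plane.

**Metabolic footprints** — per-taxon carbon flux
`F = N·(0.1·W/m + 0.273·W^0.75)` (N abundance, W fresh weight in µg, m c-p
class), summed into BFMF/FFMF/PPMF/OPMF/TNMF, the enrichment footprint Fe
(Ba1 + Fu2 guilds) and structure footprint Fs (free-living c-p 3–5), and
the **functional-footprint rhombus** centered at (SI, EI) with diagonals
Fs/k and Fe/k and area Fe·Fs/(2k²).

**Energy-flow ternary analysis** — relative channel footprints
(BFMF, FFMF, PPMF) mapped barycentrically into the fixed triangle with
base (0,0)–(100,0) and apex (50, 86.6).

**Co-occurrence networks** — all taxon pairs (within and across kingdoms)
with Spearman |ρ| > 0.6 and p < 0.05 after a ≥3-sample prevalence filter;
edge signs, network summary counts and GraphML export.

## Worked example

Simulate the phosphorus-gradient scenario (fungal-channel dominance giving
way to the bacterial channel across CK → P180) and run the faunal
analysis:

```python
from microfoodweb.simulate import simulate_phosphorus_gradient
from microfoodweb.faunal import faunal_index_table
from microfoodweb.footprints import group_footprints
from microfoodweb.energyflow import ternary_table

scenario = simulate_phosphorus_gradient(seed=42)
ann = scenario.data.annotated_nematodes()
idx = faunal_index_table(ann)
fp = group_footprints(ann, absolute_counts=True)
tern = ternary_table(fp)
summary = (idx.join(tern[["f_bact", "f_fung", "f_plant"]])
              .join(scenario.data.metadata["treatment"])
              .groupby("treatment", sort=False)
              [["EI", "SI", "CI", "MI", "f_bact", "f_fung"]]
              .mean().round(2))
print(summary)
```

```
              EI     SI     CI    MI  f_bact  f_fung
treatment
CK         50.10  49.18  70.82  2.32    0.20    0.21
P60        62.27  50.24  35.18  2.14    0.35    0.15
P120       73.51  61.06  19.25  2.11    0.47    0.10
P180       82.84  62.51   6.72  1.87    0.58    0.04
```

The channel index CI falls from ~71 to ~7 across the planted schedule —
the fungal decomposition channel giving way to the bacterial one — while
the bacterial channel fraction `f_bact` rises from 0.20 to 0.58 and the
fungal fraction falls. The scenario records its ground truth: the
closed-form CI implied by each treatment's guild composition
(`scenario.expected_ci`) is 71.4, 36.8, 17.0, 7.2.

The same analysis runs from the shell:

```bash
microfoodweb simulate --outdir sim/ --seed 42
microfoodweb indices --table sim/nematodes.tsv --traits sim/traits.tsv --out indices.tsv
microfoodweb network --tables sim/bacteria.tsv --tables sim/fungi.tsv \
    --tables sim/nematodes.tsv --out edges.tsv --stats stats.tsv
microfoodweb run --config run.yaml --outdir results/   # full pipeline
```

## Documentation

`docs/methods.md` describes the models, parameter choices, the
synthetic-data generator's assumptions, numerical conventions and known
limitations.
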