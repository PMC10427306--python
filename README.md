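# campkin

Kinship structure of mobile forager residential groups ("camps") from
genealogical data.

Hunter–gatherer populations typically live in small, fluid camps whose
members are mostly distant kin, and the degree and distribution of
relatedness within and between camps shapes the scope for kin-selected
cooperation. `campkin` turns a genealogy plus camp census data into the
standard quantitative portrait of such a population: pairwise relatedness,
shared reproductive interest, within-camp relatedness at three aggregation
levels, the dispersion of each person's kin network across camps, camp
stability, relatedness–distance decay, and spouse consanguinity and age
gaps — with permutation tests and (partial) correlations for the group
comparisons, and a synthetic-population generator for testing dispersal
hypotheses end to end.

## The statistics

**Kinship and relatedness.** For individuals *i*, *j* with pedigree links,
the kinship coefficient φ(*i*, *j*) — the probability that random alleles
drawn from each are identical by descent — is computed by the classical
tabular recurrence over a topological order of the pedigree:
φ(*i*, *j*) = ½[φ(father<sub>i</sub>, *j*) + φ(mother<sub>i</sub>, *j*)],
with φ(*i*, *i*) = ½(1 + *F*<sub>i</sub>) and missing parents treated as
unique founders. Wright's coefficient of relatedness is *r* = 2φ
(an inbreeding-normalised variant is available as an option). A
gene-dropping Monte-Carlo simulator provides an independent
identity-by-descent oracle for the recursion.

**Shared reproductive interest.** Between ego *i* and alter *j*,

> *s*(*i*, *j*) = (*r*<sub>B</sub> + *r*<sub>D</sub>) / (1 + *r*<sub>C</sub>)

where *r*<sub>B</sub> = *r*(*i*, *j*), *r*<sub>D</sub> = *r*(*i*,
spouse of *j*) and *r*<sub>C</sub> = *r*(*i*, own spouse), absent spouses
contributing zero. *s* measures how related ego expects to be to the
alter's future offspring relative to ego's own, and unlike *r* credits
affinal (in-law) ties.

**Aggregation levels.** Within-camp relatedness can be averaged per camp
then across camps (*r*<sub>group</sub>), per individual then across
individuals (*r*<sub>individual</sub>), or over all co-resident dyads
(*r*<sub>dyads</sub>); when larger camps are less related,
*r*<sub>dyads</sub> ≤ *r*<sub>individual</sub> ≤ *r*<sub>group</sub>.
All three are reported, with *r*<sub>individual</sub> as the headline.

## Worked example

Generate a synthetic bilocal population (15 camps, ~18 adults per camp,
4 generations) and run the full analysis:

```
$ campkin simulate --seed 42 --out agta_sim
wrote 484 individuals across 15 camps to agta_sim

$ campkin validate agta_sim/genealogy.csv --attributes agta_sim/attributes.csv
OK: 484 individuals, 60 founders, mean depth 2.94, max depth 4

$ campkin stats agta_sim/genealogy.csv --attributes agta_sim/attributes.csv
   statistic    value    n
     r_group 0.044223   15
r_individual 0.041129  294
     r_dyads 0.037648 3463

$ campkin campdist agta_sim/genealogy.csv \
    --attributes agta_sim/attributes.csv \
    --coordinates agta_sim/coordinates.csv
Spearman rho = -0.313, p = 0.001138 (105 camp pairs)
```

The three aggregation levels order as expected for unequal camp sizes
(dyads < individual < group), and relatedness between camps falls with
distance — camps exchange members and spouses preferentially with nearby
camps, so kin networks decay over space.

`campkin report ... --out agta_report --seed 1` writes the full bundle
(`summary.json`, per-camp and camp-pair CSVs, a run manifest recording
every methodological flag). For this population it reports, e.g., mean
adult relatedness to campmates *r* = 0.041 against a population-wide mean
of 0.022; shared reproductive interest to campmates *s* = 0.078 (affinal
ties roughly double the consanguineal figure); no sex difference in
campmate relatedness (men 0.042 vs women 0.040, two-tailed permutation
*p* = 0.687, as expected under bilocal residence); adults hold kin at
*r* ≥ 0.0625 in 8.9 of 15 camps on average; and a mean husband−wife age
gap of +3.8 y with the husband older in 80% of marriages.

The same pipeline runs unchanged on real field data supplied in the
documented CSV formats (genealogy: `id, father, mother, sex`; attributes:
`id, age, camp, spouse, adult`; plus optional visit rosters, camp
coordinates and camp covariates).

## Layout

- `src/campkin/pedigree.py` — genealogy parsing/validation, kinship
  recursion, relatedness, gene dropping
- `src/campkin/stats.py` — shared interest, aggregation, kin dispersion,
  stability, spouse summaries
- `src/campkin/inference.py` — permutation tests, correlations, partial
  correlation, haversine distances, camp-pair analysis
- `src/campkin/simulate.py` — synthetic population generator and
  deterministic fixtures
- `src/campkin/report.py` / `cli.py` — orchestration, report bundle,
  `campkin` command
- `docs/methods.md` — models, assumptions, parameter choices, limitations
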