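# faersig

Disproportionality signal detection for spontaneous adverse-event reports,
built around the FDA Adverse Event Reporting System (FAERS) quarterly
ASCII extracts. The package is aimed at pharmacovigilance and clinical
researchers who want a tested, reproducible version of the standard
"2×2-table" screening workflow: which drugs are disproportionately
co-reported with a set of adverse events of interest, which drugs signal
across *several* events at once, and how a fixed therapeutic panel (for
example the FDA-approved pulmonary-hypertension drugs) profiles across
those events.

## The statistics

For a drug *D* and event *E* over *N* deduplicated cases, with

|            | event      | no event |
|------------|------------|----------|
| drug       | a          | b        |
| no drug    | c          | d        |

the package computes the **reporting odds ratio** and **proportional
reporting ratio**,

    ROR = (a·d) / (b·c)          PRR = [a/(a+b)] / [c/(c+d)]

with log-normal (Woolf) 95% confidence intervals,

    exp( ln ROR ± z·√(1/a + 1/b + 1/c + 1/d) )
    exp( ln PRR ± z·√(1/a − 1/(a+b) + 1/c − 1/(c+d)) )

plus the Yates-corrected χ² statistic. Tables with a zero cell receive the
Haldane–Anscombe correction (+0.5 to all four cells, recorded per pair).
A pair is flagged as a *signal* under the ROR criterion (a ≥ 3 and CI
lower bound > 1) by default; the classical PRR criterion (a ≥ 3, PRR ≥ 2,
χ² ≥ 4) is available as configuration. Signals indicate reporting
disproportionality, never causation.

On top of the per-pair statistics:

* **top-N ranking** per event by report frequency (deterministic
  tie-breaks: higher ROR, then name);
* **multi-event classification**: drugs in the top-N list of *every*
  event of interest are *high* signaling drugs, drugs in exactly
  all-but-one lists are *medium* (the Venn intersection step);
* **panel profiling**: a fixed drug panel × event matrix of statistics
  with the subset of drugs signal-positive for every event.

Cases are counted once: quarterly DEMO/DRUG/REAC files are merged and
deduplicated per CASEID keeping the highest CASEVERSION (ties: latest
FDA_DT, then greatest PRIMARYID). Drug names and event terms pass through
user-supplied synonym/preferred-term tables (two-column TSV), standing in
for the licensed MedDRA dictionary.

## Worked example

Generate a synthetic report database with known planted effects, then run
the full pipeline. The default generator config plants, among others, an
odds ratio of 8 for `DRUG_A`→`DYSPNOEA`:

```sh
$ faersig simulate --out demo_sim --seed 42 --n-cases 20000
simulate: wrote 60 quarterly files for 20000 cases (2029 duplicated) to demo_sim
simulate: truth table at demo_sim/truth.tsv

$ faersig analyze demo_sim --out demo_out --roles all --top-n 10
analyze: 20000 cases, 47 pairs
analyze: high=['DRUG_F', 'DRUG_G', 'DRUG_H', 'DRUG_J', 'DRUG_K', 'DRUG_L']
analyze: medium=['DRUG_C', 'DRUG_D', 'DRUG_E', 'DRUG_I']
analyze: reports in demo_out
```

The 2,029 duplicated cases are re-emitted higher versions of existing
cases; after deduplication exactly 20,000 cases are analyzed. In
`demo_out/signal_stats.tsv` the planted pair is recovered with its CI
covering the truth (a=43 co-reports, ROR 9.62, 95% CI 6.76–13.67,
containing the planted 8):

```
drug    event      a   b    c    d      ror        ror_low   ror_high
DRUG_A  DYSPNOEA   43  136  631  19190  9.615572…  6.762720… 13.671899…
```

With ten-drug top-N lists over four events, the "high" set is simply the
drugs frequent enough to rank everywhere — with only 12 simulated drugs
that is most of the common ones; on real data N=30 against thousands of
drugs makes the intersection far more selective.

The packaged reference fixtures (published full-database top-30 lists for
post-lung-surgery dyspnoea, cough, palpitations and chest pain, and the
12-drug pulmonary-hypertension panel) can be classified directly:

```sh
$ faersig fixture-check
high (4): AMBRISENTAN, ENTRESTO, OPSUMIT, TYVASO
medium (10): COPAXONE, GILENYA, IBUPROFEN, OFEV, ORENITRAM, REMODULIN, UPTRAVI, VELETRI, XOLAIR, ZEJULA
high ∩ PH panel (3): AMBRISENTAN, MACITENTAN, TYVASO
panel drugs positive for all four events: 10 by table CIs, 9 with the text's per-drug subsets
```

i.e. four drugs rank in the top 30 of all four symptoms, ten in exactly
three; after brand→generic normalization (Opsumit→macitentan) three of
the four belong to the pulmonary-hypertension panel. The 10-vs-9 panel
count reflects a documented inconsistency in the reference tables (see
`docs/methods.md`).

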