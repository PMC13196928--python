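# Methods

## Data model and deduplication

The analysis unit is the *case* (one safety report). Quarterly extracts
are "$"-delimited text files with a header row; fields are selected by
header name, case-insensitively, never by position. Required columns:
DEMO {primaryid, caseid, caseversion, fda_dt}, DRUG {primaryid, drugname,
role_cod}, REAC {primaryid, pt}. A malformed data line (wrong field
count, missing key, unparsable version, unknown role code) is skipped and
counted with its line number; a header missing a required column is
fatal. Input bytes are decoded permissively (invalid sequences replaced),
and all names/terms are uppercased with whitespace collapsed before any
table lookup. Free text containing an embedded "$" cannot be represented
in this dialect and such lines are skipped with a log entry.

A case may appear as several versions (distinct PRIMARYIDs sharing a
CASEID). Deduplication keeps, per CASEID, the record maximizing
(CASEVERSION, FDA_DT, PRIMARYID) lexicographically. The chain is a total
order, so the retained set is invariant under input order and the
operation is idempotent. Records lacking a CASEID are retained keyed by
their PRIMARYID and counted. Drug/reaction records attached to superseded
versions are dropped and counted.

Within a case, drug mentions and reaction terms are *sets*: repeated
mentions never inflate counts. Drug roles (PS/SS/C/I) are kept per
mention; by default only suspect drugs (PS, SS) count toward exposure,
because disproportionality computed over concomitant medication dilutes
signals toward the background. The role filter is configuration
(`--roles all` includes C and I).

## Disproportionality estimators

For each drug–event pair the 2×2 table (a, b, c, d) partitions the
deduplicated case set; the comparator is every case not mentioning the
target drug, not a restricted comparator set. Estimators:

* ROR = ad/bc, CI = exp(ln ROR ± z·√(1/a+1/b+1/c+1/d)) (Woolf);
* PRR = [a/(a+b)]/[c/(c+d)], CI = exp(ln PRR ± z·√(1/a−1/(a+b)+1/c−1/(c+d)));
* χ² with Yates continuity correction,
  N·(max(0, |ad−bc|−N/2))²/((a+b)(c+d)(a+c)(b+d)), clipped at zero as in
  standard implementations (a balanced table scores exactly 0).

z defaults to 1.96, matching two-decimal published CIs; the test suite
cross-checks against statsmodels/scipy at their exact normal quantile.

**Zero cells.** When any cell is 0 the Haldane–Anscombe correction adds
0.5 to all four cells and the pair is flagged `corrected`; non-degenerate
tables are never altered. With the correction disabled, a zero cell is an
explicit error rather than an infinite estimate. A zero *margin* (drug or
event absent from the data) leaves PRR and χ² undefined (error), and
degenerate panel rows are reported as missing, never silently dropped.

For any all-positive table, ROR/PRR = (1 + a/b)/(1 + c/d), so (ROR−1) and
(PRR−1) always share a sign and |ln ROR| ≥ |ln PRR|; both facts are
enforced as property tests and explain why published pairs print PRR
slightly below ROR (8.80 vs 8.87, 16.25 vs 16.66).

**Signal criteria** are configuration, not code. Default ("ror"): a ≥ 3
and 95% CI lower bound > 1. Alternative ("prr"): a ≥ 3, PRR ≥ 2, χ² ≥ 4.
Transcribed published rows that print CIs without counts are assessed on
the CI part alone (their counts, where printed at all, are far above 3).

**Reporting.** Estimates print at two decimals, half-up, in the
`8.87(7.92-9.93)` style; full precision is kept internally and in
`signal_stats.tsv`.

## Ranking, Venn classification, panel profiling

Top-N lists rank by report frequency (a) descending with deterministic
tie-breaks (higher ROR, then drug name) and truncate to N (default 30).
The packaged reference lists are re-sorted under this rule because their
printed rank order is not frequency-sorted below the top entries; every
set-level result here depends only on list membership, never on rank
order.

Venn classification intersects the per-event lists on canonical names:
membership in all |events| lists ⇒ high signaling drug, exactly
|events|−1 ⇒ medium. Brand/generic splits must be resolved by the
normalization step first — the packaged synonym table maps
Opsumit→MACITENTAN, Adempas→RIOCIGUAT, Adcirca→TADALAFIL, and keeps the
three treprostinil products (Tyvaso, Remodulin, Orenitram) distinct,
mirroring their distinct reference rows.

Panel profiling fills the |panel|×|events| matrix and reports the drugs
positive for every event. `count_all_positive` accepts per-drug event
subsets as overrides so an externally stated reading of a published table
can be computed alongside the table-derived one.

### Known inconsistencies in the packaged reference tables

These are preserved as data, asserted in tests, and not repaired:

* the chest-pain list's Pomalyst row prints a bare ROR with no CI and a
  PRR (1.29) *above* the ROR (1.08…), which is impossible for an
  all-positive table; the fixture carries the CI stated in the reference
  text, 1.08 (0.94–1.24), and keeps the printed PRR;
* the panel table's riociguat row has all four CI lower bounds above 1
  (⇒ 10 panel drugs positive everywhere) while the accompanying per-drug
  text relates riociguat to only cough, palpitations and chest pain
  (⇒ 9). Both counts are computed; the drug-level text reading (9) is the
  one exported by the acceptance script.

## Synthetic data generator

The generator emulates the structure of the real extracts — quarterly
DEMO/DRUG/REAC files, versioned cases, role codes, multiple drugs and
reactions per case — with known planted effects, so the pipeline can be
calibrated end to end:

* exposures: independent Bernoulli per drug with configured marginals;
* events: background probability p acts through its odds p/(1−p),
  multiplied by the planted odds ratio ρ of every exposed planted drug
  (multiplicative on the odds scale). For a single-exposure case the
  exposed/unexposed reporting odds ratio is exactly ρ, making the planted
  value the estimand of the downstream ROR; with several planted drugs on
  one case the combination is an approximation of the joint effect;
* dates: uniform over 2018-01-01..2022-12-31; the quarter of the date
  decides the file a record lands in;
* duplicates: with probability `duplicate_rate` a case is re-emitted with
  CASEVERSION 2 and a later FDA date (1–90 days, clipped to the window);
* identifiers: CASEID is sequential, PRIMARYID = CASEID·100 + version, so
  dedup behaviour is transparent in fixtures;
* roles: sampled per mention from `role_mix` (default PS 0.6, SS 0.3,
  C 0.1). Roles are labels on mentions — the generator plants effects on
  *exposure* regardless of role — so analyses of synthetic data should run
  with `roles="all"`; the suspect-only default of the analysis side
  targets real extracts, where concomitant listing is incidental.

A fixed config and seed reproduce a byte-identical file set. What the
generator does **not** emulate: drug co-prescription correlation,
demographic covariates, reporter/country fields, reporting bias and
event-term misspelling. Passing calibration tests therefore demonstrates
estimator and pipeline correctness under the stated sampling model, not
robustness to the biases of real spontaneous-report data.

## Calibration conditions and problem sizes

Two preset configurations define the package's statistical checks:

* **parameter recovery** (`single_signal_config`): one drug (exposure
  0.05), one event (background 0.01), planted ρ=10, 50,000 cases; over 20
  seeded replicates the pipeline's 95% CI must cover ρ in ≥ 18. Expected
  a ≈ 230, giving a CI half-width around ±16%.
* **null calibration** (`null_calibration_config`): 30 drugs (exposure
  0.03) × 15 events (background 0.02), all pairs null, 10,000 cases; the
  flagged fraction over the 450 pairs must stay below 5% (the one-sided
  CI criterion implies ≈ 2.5% nominal).

CI coverage of the Woolf interval is additionally checked directly on
10,000 closed-form table draws (ρ=2, exposure 0.1, background 0.05,
n=10,000), required to fall in 95% ± 2%. Estimator formulas are verified
to 1e-12 against independent brute-force evaluation on the exhaustive
grid of 2×2 tables with cells in {1..6}, and against statsmodels'
`Table2x2` and scipy's corrected χ² on random tables.

## Numerical and design choices

* Half-up decimal rounding for printed estimates (banker's rounding would
  disagree with published two-decimal values).
* All orderings that reach output files are total (explicit tie-breaks,
  sorted filenames, sorted report rows), so reruns are byte-identical;
  reports are staged in a temporary directory and moved into place.
* Unmapped names/terms pass through key-normalized and are counted rather
  than dropped: a missing dictionary narrows standardization, it does not
  silently shrink the database.
* Exit codes: 0 ok, 1 user/config error, 2 data error.

## Limitations

Disproportionality on spontaneous reports measures reporting association,
not risk: no denominators of exposure, strong reporting biases, duplicate
reports beyond the version chain, confounding by indication. The package
deliberately implements only the frequentist ROR/PRR layer — Bayesian
shrinkage methods (BCPNN/IC, EBGM), time-to-onset analysis and
demographic stratification are out of scope. The packaged reference
fixtures cannot be recomputed without the multi-gigabyte source database;
they validate classification logic, while the statistical layer is
validated on synthetic data with known truth.
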