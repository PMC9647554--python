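# insomnia-cea

Decision-tree cost-effectiveness model for insomnia pharmacotherapy in
Japan.  Four strategies — lemborexant, suvorexant, zolpidem immediate
release (IR) and untreated insomnia — are compared over a six-month horizon
through three insomnia-linked adverse-event pathways: falls (with a
re-fall term and a fracture/hospitalization care pathway), motor vehicle
collisions, and workplace accidents.  The package is aimed at
health-economics analysts who want a reproducible, scriptable version of
this model class: validated parameter sets with provenance flags, exact
incremental cost-effectiveness arithmetic, and standard one-way and
probabilistic sensitivity machinery.

For each strategy *s* the tree accrues, in expectation over horizon *T*:

    QALY(s) = u·T − (1−r_s)·d·T − Σ_e E[n_e]·δ_e − P(death)·u·T/2
    Cost(s) = drug + visits + Σ_e E[n_e]·c̄_e          (JPY, payer view)

with responder rate `r_s`, insomnia disutility `d` for non-responders,
per-event counts `E[n_e]`, one-off event disutilities `δ_e`, and deaths at
the horizon midpoint.  Pairwise comparison yields dominance (cheaper and at
least as effective) or an ICER = ΔC/ΔE judged against a willingness-to-pay
of JPY 5 million/QALY; the probabilistic analysis (2000 Monte-Carlo draws)
summarises uncertainty as cost-effectiveness planes, acceptability curves
and net-monetary-benefit probabilities.  See `docs/methods.md` for the full
model description.

## Worked example

```python
import insomnia_cea as ic

params = ic.reference_parameters()          # validated, provenance-flagged
results = ic.evaluate_all(params)           # mixed-age base case
for s, r in results.items():
    print(f"{s:12s} cost={r.expected_cost_jpy:8.0f} JPY  QALY={r.expected_qaly:.4f}")

comp = ic.compare(results["lemborexant"], results["untreated"])
print(comp.label, round(comp.icer_jpy_per_qaly))
```

prints

```
lemborexant  cost=   33363 JPY  QALY=0.4114
suvorexant   cost=   37013 JPY  QALY=0.4084
zolpidem_ir  cost=   45203 JPY  QALY=0.3846
untreated    cost=   17259 JPY  QALY=0.4025
icer 1801985
```

Lemborexant costs less and yields more QALYs than either active comparator
(it is *dominant* over both), and against no treatment it buys additional
QALYs at about JPY 1.8 million each — well under the JPY 5 million
threshold, so it is cost-effective.  About thirty of the inputs behind
these numbers are published values (fall hazard chaining 0.68×1.48 and
0.85×1.48, drug costs 92/96.7/28.4 JPY/day, the 0.026 insomnia disutility,
the 56%/8% fall-care pathway, …); the rest are documented placeholder
assumptions flagged in `src/insomnia_cea/data/parameter_manifest.csv`, so
totals are indicative while orderings, dominance labels and sensitivity
structure are the meaningful outputs.

The same pipeline is available from the shell:

```sh
insomnia-cea --analysis all --seed 42 --outdir results/
```

which writes the strategy/comparison tables (base case plus age-subgroup
and WASO/LPS response-definition scenarios), per-comparison tornado tables,
the PSA scatter and the acceptability curves as CSV/JSON.

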