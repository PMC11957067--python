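"""Publication analytics: yearly growth, journals, abstract lengths, terms.

The synthetic corpus plants an exponential publication growth curve over
1998-2023; the growth report classifies years whose year-over-year change
stands one standard deviation above (below) the mean as high (low) growth.
"""

from litmap import (
    SyntheticSpec,
    abstract_length_histogram,
    generate_corpus,
    growth_report,
    journal_frequencies,
    term_frequencies,
    top_terms,
    yearly_counts,
)

corpus = generate_corpus(SyntheticSpec(seed=0)).corpus

counts = yearly_counts(corpus)
span = f"{min(counts)}-{max(counts)}"
print(f"{len(corpus)} publications over {span}; "
      f"{counts[max(counts)]} in the final year")

report = growth_report(counts)
print(f"mean year-over-year growth: {report.mean_rate:.2f} publications "
      f"(SD {report.sd_rate:.2f})")
print(f"high-growth years (start of pair): {sorted(report.high_years)}")
print("  (these are the years whose jump to the next year reached "
      "mean + 1 SD)")

lengths = abstract_length_histogram(corpus, unit="words")
modal = max(lengths, key=lengths.get)
print(f"\nmodal abstract length: {modal} words")

print("\ntop journals:")
for journal, n in journal_frequencies(corpus)[:3]:
    print(f"  {journal}: {n}")

print("\nmost frequent abstract terms (stop words removed):")
for term, n in top_terms(term_frequencies(corpus), k=5):
    print(f"  {term}: {n}")
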