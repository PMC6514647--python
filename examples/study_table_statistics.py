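"""Agreement statistics from the packaged study tables.

Loads the shipped model-vs-in-situ comparison tables for a 2016 corn season
(LAI against a ceptometer, surface temperature against an infrared
thermometer, and per-location daily ETa) and recomputes the agreement
statistics and per-date field-average ETa. r2 is the squared Pearson
correlation; MBE is model minus measurement; both the paired RMSE and the
regression standard error are reported because published scatterplot "RMSE"
values are often the latter.
"""

from metricet import pipeline

stats, eta_by_date = pipeline.fixture_report()
print(stats.round(3).to_string(index=False))
print()
print("per-date field-average ETa (mm/day) from the five plot values:")
print(eta_by_date.round(2).to_string(index=False))
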