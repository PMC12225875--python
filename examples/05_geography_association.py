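"""Test association between geography and toxin loss on the venom survey.

The packaged 27-specimen survey records, per specimen, the cohort (west or
east of the Continental Divide) and the Western-blot phenotype of the P1
metalloproteinase.  The 2x2 table of cohort x (low/undetected vs detected)
is tested with the continuity-corrected chi-squared statistic.
"""

from toxinloss.integrate import load_survey_labels, table_from_labels, yates_chi_squared

labels = load_survey_labels()
table = table_from_labels(labels)
print("2x2 table (rows: west/east; columns: low-or-undetected/detected):")
print(f"  west: {table.a:2d} low, {table.b:2d} detected   ({table.a}/{table.a + table.b})")
print(f"  east: {table.c:2d} low, {table.d:2d} detected   ({table.c}/{table.c + table.d})")

res = yates_chi_squared(table)
print(f"\ncontinuity-corrected chi2 = {res.chi2:.2f}, df = {res.df}, p = {res.p:.4f}")
uncorrected = yates_chi_squared(table, corrected=False)
print(f"uncorrected chi2 = {uncorrected.chi2:.2f} (for comparison)")
print("\nLoss of the toxin is strongly enriched west of the Continental Divide.")
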