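"""Apply the exclusion cascade to the bundled 27-variant frequency table.

Candidate variants are screened for internal-vs-external control frequency
discrepancies: a variant is excluded when the absolute difference exceeds
0.10 AND the fold change exceeds 2 (an external frequency of 0 counts as
infinite fold change). Tri-allelic variants are exempt — their split
records make external comparisons ambiguous — and are only flagged
inconclusive.
"""

import pandas as pd

from hervtriage import diamond_screen, load_common_variant_table

table = load_common_variant_table()
for _, row in table.iterrows():
    ext = None if pd.isna(row["maf_external"]) else float(row["maf_external"])
    exclude, inconclusive = diamond_screen(
        row["maf_control_internal"], ext, bool(row["tri_allelic"])
    )
    if exclude or inconclusive:
        mark = "excluded" if exclude else "inconclusive (tri-allelic)"
        print(
            f"{row['name']:<16} {row['gene']:<10} internal="
            f"{row['maf_control_internal']:.3f} external="
            f"{'NA' if ext is None else f'{ext:.3f}'}  -> {mark}"
        )
n_excl = sum(
    diamond_screen(
        r["maf_control_internal"],
        None if pd.isna(r["maf_external"]) else float(r["maf_external"]),
        bool(r["tri_allelic"]),
    )[0]
    for _, r in table.iterrows()
)
print(f"\n{n_excl} of {len(table)} variants excluded by the database screen.")
print(
    "Variants whose control-cohort frequency cannot be corroborated by an "
    "independent reference are dropped before functional follow-up."
)
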