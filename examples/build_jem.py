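"""Build a probability-of-shift-work job-exposure matrix from survey records.

Generates a synthetic labour-survey extract, tabulates shift-worker counts
per occupation code at the specific (4-digit) and broad (2-digit) levels,
and applies confidentiality suppression to small cells.
"""

import shiftjem as sj

survey = sj.generate_survey(sj.SurveyConfig(seed=1))
specific, broad = sj.build_jem_pair(survey)

print(f"survey: {len(survey)} respondents, "
      f"{survey['occupation_code'].nunique()} occupation codes")
print(f"specific table: {len(specific)} cells, "
      f"{sum(c.suppressed for c in specific)} suppressed")
print(f"broad table:    {len(broad)} cells, "
      f"{sum(c.suppressed for c in broad)} suppressed\n")

print("code   level     n_total n_shift  p_shift")
for cell in sorted(specific, key=lambda c: c.code)[:6]:
    p = "(concealed)" if cell.p_shift is None else f"{cell.p_shift:.3f}"
    print(f"{cell.code:6} {cell.level:9} {cell.n_total:7} {cell.n_shift:7}  {p}")

# A suppressed specific cell still has a releasable broad parent: the
# hierarchical fallback that downstream linkage exploits.
suppressed = next(c for c in specific if c.suppressed)
parent = sj.broad_code(suppressed.code)
print(f"\n{suppressed.code} is concealed (n={suppressed.n_total}); its broad "
      f"group {parent} releases p_shift = {broad.lookup(parent):.3f}")
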