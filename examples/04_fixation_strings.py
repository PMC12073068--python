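"""Resolving ambiguous fixations into an AOI search string.

Expanded AOI annotations overlap, so a fixation can match several AOIs.
The minimum-transition assignment (layered DAG, edge cost 1 per label
change) picks the reading with the fewest AOI switches: ambiguous
fixations flanked by unambiguous ones inherit the flanking AOI.
"""

from retinagaze import collapse_runs
from retinagaze.strings import LabelledFixation, resolve_labels

# two fixations clearly in the inferior arcade, three in the arcade/macula
# overlap: the cheapest path keeps them all in the arcade (0 transitions)
fixations = [
    LabelledFixation(frozenset(c), duration=250.0)
    for c in [{"I"}, {"I"}, {"I", "M"}, {"I", "M"}, {"I", "M"}]
]
out = resolve_labels(fixations, response_id="demo")
print("candidates :", [sorted(f.candidates) for f in fixations])
print("resolved   :", "".join(out.resolved), f"({out.cost} transitions)")
print("pattern    :", out.pattern)

# run collapsing: repeats merge, background (B) drops out
resolved = list("MMBSSDD")
print(f"\nresolved sequence {''.join(resolved)} -> pattern {collapse_runs(resolved)!r}")
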