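#!/usr/bin/env python
"""Differential expression for the three pairwise contrasts.

Loads the simulated counts from results/run/, normalizes to log2-CPM with
median-of-ratios effective library sizes, and runs the moderated t per
contrast: donor vs recipient monoculture (the donor-high catalog source),
contact culture vs monoculture, and conditioned media vs monoculture.
Ranked DEG tables land in results/run/.
"""

from pathlib import Path

from cocultnet import differential, io

OUT = Path(__file__).resolve().parent.parent / "results" / "run"

expr = io.read_expression(OUT / "expression.tsv", OUT / "annotations.tsv")
libs = differential.effective_library_sizes(expr)
log2 = differential.normalize_log2cpm(expr, library_sizes=libs)

rmono = expr.samples_where(condition="recipient_mono")
contrasts = {
    "donor_vs_mono": expr.samples_where(condition="donor_mono"),
    "cc_vs_mono": expr.samples_where(condition="recipient_cc"),
    "cm_vs_mono": expr.samples_where(condition="recipient_cm"),
}
for name, group_b in contrasts.items():
    res = differential.de_test(log2, rmono, group_b, engine="moderated")
    res.write_tsv(OUT / f"de_{name}.tsv")
    hits = differential.filter_deg(res, 2.0, 0.05, "up", name)
    print(f"{name}: {len(hits)} genes up at |log2FC|>=2, adj p<0.05")
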