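"""Simulate a spatial lineage tracing dataset and look at what it contains.

Generates one colony under the benchmark conditions (30 cells, 216 frames,
diffusion rate 1.5, division displacement 6.68, 10 CRISPR target sites at
edit rate 0.006/frame) and writes the four standard files: Newick tree,
character matrix, leaf locations, and the ground-truth JSON.
"""

import json
import tempfile
from pathlib import Path

from sdtrace import make_fixture, parse_newick, read_character_matrix
from sdtrace.trees import MISSING

out_dir = Path(tempfile.mkdtemp(prefix="sdtrace_example_"))
paths = make_fixture("default", seed=7, out_dir=out_dir)

tree = parse_newick(Path(paths["tree"]).read_text())
matrix = read_character_matrix(paths["matrix"])
truth = json.loads(Path(paths["truth"]).read_text())

n_edited = (matrix.data > 0).mean()
n_missing = (matrix.data == MISSING).mean()
print(f"dataset written to {out_dir}")
print(f"tree: {tree.n_leaves} cells, "
      f"{len(tree.bifurcations())} divisions over "
      f"{truth['config']['tau_end']:.0f} frames")
print(f"character matrix: {matrix.n_cells} x {matrix.n_sites}, "
      f"{n_edited:.0%} edited entries, {n_missing:.0%} missing ('?')")
print("generating parameters:",
      {k: truth["config"][k] for k in ("sigma", "r", "lam", "nu", "phi")})
# The edited fraction reflects lambda * tau ~ 1.3 expected edits per site
# per lineage; the missing fraction combines heritable silencing (nu) with
# per-cell dropout (phi).
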