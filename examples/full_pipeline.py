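"""End-to-end run: structure + family alignment -> the three report tables.

Generates a synthetic single-helix model with an axial ligand and a matching
six-member family alignment, then runs the whole pipeline: binding set,
surface set, per-group variation, size profiles, selected-site summary and
the statistics JSON.
"""

import json
import tempfile
from pathlib import Path

import numpy as np

from cspstruct import BundleSpec, build_helical_bundle
from cspstruct.pipeline import RunConfig, run_pipeline
from cspstruct.synthetic_data import bundle_pdb_text

workdir = Path(tempfile.mkdtemp(prefix="cspstruct_example_"))

spec = BundleSpec(n_helices=1, residues_per_helix=30, bundle_radius=5.0,
                  ligand_length=20, seed=1)
(workdir / "model.pdb").write_text(bundle_pdb_text(spec))
_, seqs = build_helical_bundle(spec)
ref_seq = seqs["A"]

rng = np.random.default_rng(7)
letters = list("ACDEFGHIKLMNPQRSTVWY")
records = []
for group in ("1", "2"):
    for species in ("Aant", "Bant", "Cant"):
        seq = list(ref_seq)
        if not (group == "1" and species == "Aant"):
            for pos in rng.choice(30, size=6, replace=False):
                seq[pos] = rng.choice(letters)
        records.append((f"{species}CSP{group}", "".join(seq)))
(workdir / "family.fasta").write_text(
    "".join(f">{rid}\n{s}\n" for rid, s in records))

config = RunConfig(pdb=str(workdir / "model.pdb"),
                   alignment=str(workdir / "family.fasta"),
                   reference_id="AantCSP1", ligand_names=["LIG"],
                   selected_sites=[2, 5, 9],
                   outdir=str(workdir / "out"), seed=1)
summary = run_pipeline(config)

print(f"reports written to {workdir / 'out'}")
print(json.dumps(summary, indent=2))
print((workdir / "out" / "table1.tsv").read_text())
# table1: per-group charge variation; table2: per-member pocket size
# profiles; table3: selected-site accessibility/variant summary; stats.json:
# the chi-square and Fisher results backing the claims.
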