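"""Run the full pipeline end to end on emitted fixtures.

Stages: hit-table ingest -> architecture assembly -> anchor/insert
extraction -> LCR zoning -> composition clustering -> homology gate ->
clade partition -> per-protein report.  The run is deterministic given
(inputs, config, seed).
"""

import tempfile
from pathlib import Path

from archetyper import RunConfig, SyntheticSpec, emit_fixtures, \
    run_pipeline

with tempfile.TemporaryDirectory() as td:
    d = Path(td)
    spec = SyntheticSpec(n_per_subfamily=5, seed=42)
    emit_fixtures(spec, d / "fx")
    ids = spec.protein_ids()

    config = RunConfig(fasta=str(d / "fx" / "proteins.fasta"),
                       hits=str(d / "fx" / "hits.tsv"),
                       tree=str(d / "fx" / "tree.nwk"),
                       outdir=str(d / "out"),
                       references=[ids["bmsp"][0], ids["pif"][0]],
                       reference_id=ids["pif"][0])
    report = run_pipeline(config)

    print(report.per_protein[["protein_id", "n_vwa", "tiers", "lg_status",
                              "insert_length", "subfamily"]]
          .head(8).to_string(index=False))
    print(f"\n{len(report.per_protein)} proteins summarized, "
          f"{report.n_failed} skipped")
    print(f"family clade: {len(report.family_leaves)} leaves; "
          f"{len(report.subfamilies)} subfamilies")
    print("outputs written:",
          sorted(p.name for p in (d / "out").iterdir()))
# Every protein appears exactly once; subfamily labels come from the
# support-threshold partition and match the planted membership.
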