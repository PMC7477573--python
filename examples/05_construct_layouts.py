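"""Build and validate promoter/operator cassette layouts.

Builds a core cassette (17-bp operator between the -35/-10 hexamers), a
series cassette (core + proximal operator at +15 bp), and a two-channel
parallel record with distinct ribozyme insulators, then runs the layout
validator on each and writes the parallel record as a GenBank file.  The
reported spacings are the layout contract: 17 bp between hexamers around a
core operator, 15 bp from the -10 box to a proximal operator.
"""

import io

from txlogic.constructs import (
    OPERATOR_SEQS, PL, TRC, build_parallel_record, build_series_cassette,
    build_core_promoter, validate_layout,
)

core = build_core_promoter(TRC, OPERATOR_SEQS["O1"], operator_label="O1")
series = build_series_cassette(OPERATOR_SEQS["Oagg"], OPERATOR_SEQS["Ottg"],
                               core_label="Oagg", proximal_label="Ottg")
ch2 = build_core_promoter(PL, OPERATOR_SEQS["Ottg"], operator_label="Ottg",
                          insulator="RiboJ10")
parallel = build_parallel_record(series, ch2)

for label, rec in (("core", core), ("series", series), ("parallel", parallel)):
    rep = validate_layout(rec)
    print(f"{label:<9} -35={rep.minus35_seqs} -10={rep.minus10_seqs}")
    print(f"          spacings={rep.core_spacings} proximal_offsets={rep.proximal_offsets} "
          f"insulators={rep.insulators} violations={rep.violations}")

buf = io.StringIO()
parallel.write(buf, "genbank")
gb = buf.getvalue()
print(f"GenBank record: {len(parallel.sequence)} bp, "
      f"{len(parallel.features)} features, {len(gb.splitlines())} lines")
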