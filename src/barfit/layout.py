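"""Declared amplicon read layout shared by the FASTQ writer and parser.

Reads have the structure::

    [forward index (9-12 bp)][anchor1 (8 bp)][barcode (20 bp)][anchor2 (8 bp)][reverse index (9-12 bp)]

The two fixed anchors stand in for the constant amplicon sequence flanking the
20 bp lineage barcode.  Index lengths vary per sample (9-12 bp) and are known
from the sample sheet, so all matching is position-fixed: a read is assigned
iff the forward index, both anchors, the 20-mer and the reverse index all
match exactly.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ReadLayout:
    anchor1: str = "GTCGACCT"
    anchor2: str = "AGGTCGAC"
    barcode_length: int = 20
    min_index_length: int = 9
    max_index_length: int = 12

    def read_length(self, fwd_len: int, rev_len: int) -> int:
        return fwd_len + len(self.anchor1) + self.barcode_length + len(self.anchor2) + rev_len

    def assemble(self, fwd_index: str, barcode: str, rev_index: str) -> str:
        return fwd_index + self.anchor1 + barcode + self.anchor2 + rev_index


DEFAULT_LAYOUT = ReadLayout()
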