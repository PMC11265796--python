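"""Circular k-mer census of a user-supplied circRNA sequence.

Usage: python examples/05_real_circrna_check.py <circ.fa>

For the human circHIPK3 exon (hg19 chr11:33,307,958-33,309,057; FASTA not
bundled, supply your own), the circular 7-mer census yields 1032 unique
7-mers, none occurring more than three times, and the literal 11-mer
AGGCCCCCAGC is present.
"""

import sys

from circmotif.io import read_fasta
from circmotif.seqkmer import CircularSequence, ScanParams, enumerate_kmers, scan_motif

if len(sys.argv) != 2:
    sys.exit(__doc__)

for name, seq in read_fasta(sys.argv[1]).items():
    circ = CircularSequence(name, seq)
    table = enumerate_kmers(circ, 7)
    hits = scan_motif(seq + seq[:10], "AGGCCCCCAGC", ScanParams(0), sequence_id=name)
    print(f"{name}: length {len(circ)} nt")
    print(f"  circular 7-mer windows: {table.n_windows}")
    print(f"  unique 7-mers:          {table.n_unique}")
    print(f"  max 7-mer multiplicity: {table.max_multiplicity}")
    print(f"  literal AGGCCCCCAGC occurrences (junction included): {len(hits)}")
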