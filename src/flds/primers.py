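"""Primer sequences of the FLDS library chemistry.

The PC3-T7 loop primer is ligated to every dsRNA fragment 3' end; PC2 is
the 17-mer used for single-primer PCR of the resulting cDNA.  PC2 sequence
adjacent to a read end therefore marks a ligated fragment terminus, which
is what terminal-end confirmation looks for after trimming.
"""

from flds.formats_io import reverse_complement

PC2 = "CCGAATTCCCGGGATCC"
PC2_RC = reverse_complement(PC2)

DEFAULT_PRIMER_SET = (PC2, PC2_RC)
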