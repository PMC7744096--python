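"""Library chemistry constants shared by the simulator and the read processor.

The 3' DNA adaptor is ligated to intact (CCA-ended) tRNA 3' ends after
periodate treatment; the second adaptor is ligated to the 3' end of the
cDNA during library construction and therefore appears at the 3' end of
mate 2 when the insert is shorter than the read length.
"""

# 5'-adenylated DNA adaptor ligated to the tRNA 3' end.
ADAPTOR_3P = "TGGAATTCTCGGGTGCCAAGG"

# 5'-phosphorylated DNA adaptor ligated to the cDNA 3' end (read-through
# adaptor of mate 2).
ADAPTOR_RT = "AGATCGGAAGAGCGTCGTGTAGGGA"
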