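# SYNTHETIC demonstration motif table.
#
# The labels and diagnostic variants below are invented for documentation and
# testing only — they are NOT real haplogroup motifs.  For real analyses,
# supply your own table in this format: one entry per haplogroup, with its
# parent label (null at the root) and the diagnostic control-region variants
# that define its branch relative to the parent, in position+base notation.
ROOT: {parent: null, motif: ""}
A:    {parent: ROOT, motif: "16129A"}
A1:   {parent: A,    motif: "16187T 16189C"}
A1a:  {parent: A1,   motif: "16223T"}
B:    {parent: ROOT, motif: "16278G"}
B1:   {parent: B,    motif: "16311C"}
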