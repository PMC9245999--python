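# 30-amplicon slow/moderate-mutability forensic Y-STR panel:
# 26 single-copy loci + 2 multi-copy loci (DYS385a/b, DYS527a/b).
DYS456	1	moderate
DYS389I	1	slow
DYS390	1	slow
DYS389II	1	moderate
DYS458	1	moderate
DYS19	1	slow
DYS385a/b	2	moderate
DYS393	1	slow
DYS391	1	slow
DYS439	1	moderate
DYS635	1	moderate
DYS392	1	slow
YGATAH4	1	slow
DYS437	1	slow
DYS438	1	slow
DYS448	1	slow
DYS549	1	moderate
DYS447	1	moderate
DYS388	1	slow
DYS444	1	moderate
DYS460	1	moderate
DYS481	1	moderate
DYS520	1	moderate
DYS522	1	moderate
DYS643	1	slow
DYS533	1	moderate
DYS557	1	moderate
DYS527a/b	2	moderate
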