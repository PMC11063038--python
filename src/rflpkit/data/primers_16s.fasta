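>16S_rRNA-F
TGACTTACGTCGATTTGAAC
>16S_rRNA-R
GACTGTACAAAGGTAGCATAAT
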