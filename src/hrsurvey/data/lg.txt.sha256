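7e90b410de3963dfcd3000fd48bd4fc3078574ca3f4945b4cc653f20c04f4f5c  lg.txt
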