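pattern,action
"#{2,}",remove
"original result\s*:",remove
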