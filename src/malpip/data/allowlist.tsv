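item_id	reason
enoxaparin	Printed round-1 CI (2.80-4.87) straddles the 3.0 threshold yet the item is printed as a round-1 exclusion with no round-2 statistics or adjudication footnote; the published label is carried as-is and flagged as a known anomaly (probable typographical CI bound).
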