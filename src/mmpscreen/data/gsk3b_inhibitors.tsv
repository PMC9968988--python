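compound_id	target_id	pic50	is_primary
CHIRON	GSK3B	9.12	true
6BIO	GSK3B	8.6	true
AZ1	GSK3B	9.5	true
AZ2	GSK3B	8.2	true
AZ3	GSK3B	7.9	true
AZ4	GSK3B	10	true
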