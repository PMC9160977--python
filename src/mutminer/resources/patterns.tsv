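pattern_id	mention_kind	regex
sub_one_letter	protein_substitution	(?<![A-Za-z0-9])(?P<ref>[ACDEFGHIKLMNPQRSTVWY])(?P<pos>[1-9][0-9]*)(?P<alt>[ACDEFGHIKLMNPQRSTVWY])(?![A-Za-z0-9])
sub_one_letter_arrow	protein_substitution	(?<![A-Za-z0-9])(?P<ref>[ACDEFGHIKLMNPQRSTVWY])(?P<pos>[1-9][0-9]*)\s*(?:→|->)\s*(?P<alt>[ACDEFGHIKLMNPQRSTVWY])(?![A-Za-z0-9])
nonsense_stop	nonsense	(?<![A-Za-z0-9])(?P<ref>[ACDEFGHIKLMNPQRSTVWY])(?P<pos>[1-9][0-9]*)(?P<alt>\*|X\b|(?i:amber|ochre|opal)\b)
sub_three_letter	protein_substitution	(?<![A-Za-z0-9])(?P<ref>(?i:{AA3}))(?:\s*[-–]\s*|\s+)?(?P<pos>[1-9][0-9]*)(?:\s*(?:[-–]|→|->)\s*|\s+)?(?P<alt>(?i:{AA3}))(?![A-Za-z0-9])
sub_full_name	protein_substitution	(?<![A-Za-z0-9])(?P<ref>(?i:{AANAME}))\s*[-–]\s*(?P<pos>[1-9][0-9]*)\s*[-–]\s*(?P<alt>(?i:{AANAME}))(?![A-Za-z0-9])
dna_substitution	dna_substitution	(?<![A-Za-z0-9])(?:c\.)?(?P<pos>[1-9][0-9]*)(?P<ref>[ACGT])\s*>\s*(?P<alt>[ACGT])(?![A-Za-z0-9])
simple_deletion	deletion	(?<![A-Za-z0-9])(?:[1-9][0-9]*\s?(?i:del)|(?i:del)\s?[1-9][0-9]*)(?![A-Za-z0-9])
simple_insertion	insertion	(?<![A-Za-z0-9])(?:[1-9][0-9]*\s?(?i:ins)|(?i:ins)\s?[1-9][0-9]*)(?![A-Za-z0-9])
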