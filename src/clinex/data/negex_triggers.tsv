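# Default negation trigger lexicon, one phrase and role per line.
# Roles: PRE (negates following terms), POST (negates preceding terms),
# PSEUDO (looks like a trigger but is ignored), TERM (ends a negation scope).
# Users may replace this file with their own list via the same format.
no	PRE
not	PRE
without	PRE
absence of	PRE
no evidence of	PRE
no sign of	PRE
no signs of	PRE
no history of	PRE
denies	PRE
denied	PRE
deny	PRE
negative for	PRE
free of	PRE
never developed	PRE
never had	PRE
rules out	PRE
ruled out	PRE
cannot	PRE
unremarkable for	PRE
was ruled out	POST
is ruled out	POST
unlikely	POST
was excluded	POST
not be ruled out	PSEUDO
no increase	PSEUDO
no change	PSEUDO
no significant change	PSEUDO
not only	PSEUDO
not cause	PSEUDO
not certain if	PSEUDO
not certain whether	PSEUDO
gram negative	PSEUDO
but	TERM
however	TERM
although	TERM
though	TERM
except	TERM
apart from	TERM
aside from	TERM
which	TERM
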