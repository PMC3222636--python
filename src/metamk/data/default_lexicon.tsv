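# metamk default clue lexicon
# Columns (tab-separated):
#   pattern	dimension	value	event_types	priority
# pattern: space-separated tokens; hyphens split tokens; placeholders {NUM}
#   (numeral) and {PCT} (percentage) match at token level.
# dimension: KT | CL | Polarity | Manner | Source
# event_types: comma-separated event-type labels the clue is restricted to,
#   or * for unconditioned.
# priority: higher outranks lower before trigger proximity is considered;
#   0 for almost everything, so proximity to the trigger normally decides.
#   Explicit-Neutral manner markers carry -1 so that an explicit High/Low
#   indication outbids an explicit neutral one.
suggest	KT	Analysis	*	0
show	KT	Analysis	*	0
demonstrate	KT	Analysis	*	0
demonstrated	KT	Analysis	*	0
showed	KT	Analysis	*	0
shown	KT	Analysis	*	0
may	KT	Analysis	*	0
can	KT	Analysis	*	0
associated	KT	Analysis	*	0
indicate	KT	Analysis	*	0
revealed	KT	Analysis	*	0
suggesting	KT	Analysis	*	0
report	KT	Analysis	*	0
identified	KT	Analysis	*	0
thus	KT	Analysis	*	0
indicated	KT	Analysis	*	0
indicating	KT	Analysis	*	0
examined	KT	Investigation	*	0
investigated	KT	Investigation	*	0
analyzed	KT	Investigation	*	0
studied	KT	Investigation	*	0
to determine	KT	Investigation	*	0
tested	KT	Investigation	*	0
measured	KT	Investigation	*	0
monitored	KT	Investigation	*	0
to investigate	KT	Investigation	*	0
to examine	KT	Investigation	*	0
to study	KT	Investigation	*	0
analysis	KT	Investigation	*	0
studies	KT	Investigation	*	0
to identify	KT	Investigation	*	0
investigate	KT	Investigation	*	0
found	KT	Observation	*	0
observed	KT	Observation	*	0
detected	KT	Observation	*	0
detectable	KT	Observation	*	0
seen	KT	Observation	*	0
noted	KT	Observation	*	0
find	KT	Observation	*	0
detect	KT	Observation	*	0
findings	KT	Observation	*	0
observations	KT	Observation	*	0
finding	KT	Observation	*	0
exhibit	KT	Observation	*	0
known	KT	Fact	*	0
stimulate	KT	Method	*	0
addition	KT	Method	*	0
can	CL	L2	*	0
suggest	CL	L2	*	0
indicate	CL	L2	*	0
suggesting	CL	L2	*	0
ability	CL	L2	*	0
indicated	CL	L2	*	0
appears	CL	L2	*	0
able	CL	L2	*	0
indicating	CL	L2	*	0
likely	CL	L2	*	0
normally	CL	L2	*	0
often	CL	L2	*	0
frequently	CL	L2	*	0
may	CL	L1	*	0
might	CL	L1	*	0
could	CL	L1	*	0
possible	CL	L1	*	0
potential	CL	L1	*	0
possibility	CL	L1	*	0
possibly	CL	L1	*	0
potentially	CL	L1	*	0
perhaps	CL	L1	*	0
propose	CL	L1	*	0
sometimes	CL	L1	*	0
rarely	CL	L1	*	0
scarcely	CL	L1	*	0
not	Polarity	Negative	*	0
no	Polarity	Negative	*	0
independent	Polarity	Negative	Correlation,Regulation,Positive_Regulation	0
without	Polarity	Negative	*	0
failed	Polarity	Negative	*	0
nor	Polarity	Negative	*	0
absence	Polarity	Negative	*	0
neither	Polarity	Negative	*	0
unaffected	Polarity	Negative	*	0
lack	Polarity	Negative	*	0
un	Polarity	Negative	*	0
unable	Polarity	Negative	*	0
independently	Polarity	Negative	Correlation,Regulation,Positive_Regulation	0
resistant	Polarity	Negative	*	0
fails	Polarity	Negative	*	0
normal	Polarity	Negative	Negative_Regulation	0
silent	Polarity	Negative	Positive_Regulation	0
significantly	Manner	High	*	0
potent	Manner	High	*	0
markedly	Manner	High	*	0
rapidly	Manner	High	*	0
strongly	Manner	High	*	0
rapid	Manner	High	*	0
significant	Manner	High	*	0
completely	Manner	High	*	0
strong	Manner	High	*	0
high	Manner	High	*	0
high levels	Manner	High	*	0
overexpression	Manner	High	Gene_Expression	0
highly	Manner	High	*	0
marked	Manner	High	*	0
dramatically	Manner	High	*	0
{NUM}-fold	Manner	High	*	0
by {PCT}	Manner	High	*	0
little	Manner	Low	*	0
low	Manner	Low	*	0
little or no	Manner	Low	*	0
low levels	Manner	Low	*	0
weak	Manner	Low	*	0
limited	Manner	Low	*	0
low level	Manner	Low	*	0
weakly	Manner	Low	*	0
minimal	Manner	Low	*	0
only a partial	Manner	Low	*	0
no significant	Manner	Low	*	0
partially	Manner	Low	*	0
barely	Manner	Low	*	0
to a lesser extent	Manner	Low	*	0
not significant	Manner	Low	*	0
less important	Manner	Low	*	0
{NUM}-fold less	Manner	Low	*	0
{NUM}-fold lower	Manner	Low	*	0
normal	Manner	Neutral	*	-1
medium	Manner	Neutral	*	-1
previously	Source	Other	*	0
has been	Source	Other	*	0
recently	Source	Other	*	0
have been	Source	Other	*	0
previous studies	Source	Other	*	0
recent studies	Source	Other	*	0
recent	Source	Other	*	0
previous	Source	Other	*	0
our previous studies	Source	Other	*	0
earlier	Source	Other	*	0
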