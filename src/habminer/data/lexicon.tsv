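# surface	lemma	pos
the	the	DT
a	a	DT
an	an	DT
this	this	DT
that	that	DT
these	these	DT
those	those	DT
its	its	PRP$
their	their	PRP$
it	it	PRP
they	they	PRP
and	and	CC
or	or	CC
of	of	IN
in	in	IN
from	from	IN
with	with	IN
through	through	IN
as	as	IN
by	by	IN
on	on	IN
at	at	IN
is	be	VBZ
was	be	VBD
are	be	VBP
were	be	VBD
be	be	VB
can	can	MD
has	have	VBZ
lives	live	VBZ
invades	invade	VBZ
infect	infect	VBP
found	find	VBN
isolated	isolate	VBN
obtained	obtain	VBN
spread	spread	VBN
examined	examine	VBN
analyzed	analyze	VBN
invading	invade	VBG
causing	cause	VBG
highly	highly	RB
initially	initially	RB
not	not	RB
infectious	infectious	JJ
aerobic	aerobic	JJ
severe	severe	JJ
oral	oral	JJ
nasal	nasal	JJ
small	small	JJ
wet	wet	JJ
iron-rich	iron-rich	JJ
respiratory	respiratory	JJ
gastrointestinal	gastrointestinal	JJ
probiotic	probiotic	JJ
pharyngeal	pharyngeal	JJ
ancient	ancient	JJ
infected	infected	JJ
capable	capable	JJ
normal	normal	JJ
bodily	bodily	JJ
bacterium	bacterium	NN
contact	contact	NN
air	air	NN
strain	strain	NN
river	river	NN
sediment	sediment	NN
group	group	NN
tract	tract	NN
rhizosphere	rhizosphere	NN
cavity	cavity	NN
skin	skin	NN
lesion	lesion	NN
disease	disease	NN
patient	patient	NN
stem	stem	NN
nodule	nodule	NN
infant	infant	NN
mummy	mummy	NN
tissue	tissue	NN
fluid	fluid	NN
environment	environment	NN
mouse	mouse	NN
cheese	cheese	NN
human	human	NN
gut	gut	NN
mucosa	mucosa	NN
intestine	intestine	NN
water	water	NN
ground	ground	NN
surface	surface	NN
animal	animal	NN
organism	organism	NN
flora	flora	NN
component	component	NN
species	species	NN
genus	genus	NN
feces	feces	NNS
products	product	NNS
organisms	organism	NNS
animals	animal	NNS
plants	plant	NNS
plant	plant	NN
humans	human	NNS
diseases	disease	NNS
bacteria	bacterium	NNS
tissues	tissue	NNS
mummies	mummy	NNS
cavities	cavity	NNS
Brucella	Brucella	NNP
Borrelia	Borrelia	NNP
Bordetella	Bordetella	NNP
Bifidobacterium	Bifidobacterium	NNP
Lactobacillus	Lactobacillus	NNP
Listeria	Listeria	NNP
Streptococcus	Streptococcus	NNP
Azospirillum	Azospirillum	NNP
Bradyrhizobium	Bradyrhizobium	NNP
Thiobacillus	Thiobacillus	NNP
Aeschynomene	Aeschynomene	NNP
Ixodes	Ixodes	NNP
Germany	Germany	NNP
Europe	Europe	NNP
Lyme	Lyme	NNP
canis	canis	NN
petrii	petrii	NN
burgdorferi	burgdorferi	NN
longum	longum	NN
casei	casei	NN
scapularis	scapularis	NN
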