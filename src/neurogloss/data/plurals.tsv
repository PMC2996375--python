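# singular -> plural forms for the head nouns of glossary surfaces.
# Latin/Greek irregulars first, then the regular forms needed to
# pluralize multi-word surfaces ending in these nouns.
ganglion	ganglia
ommatidium	ommatidia
soma	somata
ocellus	ocelli
plexus	plexuses
nucleus	nuclei
cortex	cortices
calyx	calyces
pedunculus	pedunculi
perikaryon	perikarya
glomerulus	glomeruli
rhopalium	rhopalia
phaosome	phaosomes
stemma	stemmata
body	bodies
neuropil	neuropils
eye	eyes
cell	cells
neuron	neurons
neurite	neurites
bundle	bundles
commissure	commissures
connective	connectives
nerve	nerves
organ	organs
synapse	synapses
lobe	lobes
cord	cords
tube	tubes
precursor	precursors
substance	substances
neuroblast	neuroblasts
tract	tracts
system	systems
complex	complexes
bridge	bridges
receptor	receptors
photoreceptor	photoreceptors
fiber	fibers
cylinder	cylinders
nervenfaser	nervenfasern
brain	brains
retina	retinae
cone	cones
tapetum	tapeta
lens	lenses
iris	irides
sheath	sheaths
effector	effectors
afferent	afferents
efferent	efferents
interneuron	interneurons
motoneuron	motoneurons
neurotroch	neurotrochs
gastrotroch	gastrotrochs
cilium	cilia
canal	canals
rhabdom	rhabdoms
apparatus	apparatuses
junction	junctions
orthogon	orthogons
syncerebrum	syncerebra
neuromere	neuromeres
tetraneurion	tetraneuria
ending	endings
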