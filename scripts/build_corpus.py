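"""Dev-time generator for src/neurogloss/data/glossary.inc.

Holds the structured transcription of the 47 glossary entries and the
register table as Python literals, builds a KnowledgeBase and serializes
it through write_corpus so the shipped file is canonical by construction.
Run from the repo root:  python scripts/build_corpus.py
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from neurogloss.model import (
    KnowledgeBase, ParentKind, ParentRef, PartStatement, Provenance,
    Quantifier, RegisterRow, SideEntry, TermEntry,
)
from neurogloss.corpus import write_corpus, parse_corpus

S = Quantifier.SOME
E = Quantifier.EVERY
MAIN = ParentKind.MAIN_TERM
PRIM = ParentKind.PRIMITIVE
CLUS = ParentKind.CLUSTER_OF

# (id, label, (genus kind, target), [(whole, quant)...], [differentia...],
#  [discouraged...], [def_xrefs...])
ENTRIES = [
    (1, "apical organ", (MAIN, "sensory organ"), [("nervous system", S)],
     ["It comprises an apical ciliary tuft and receptor cells.",
      "It is located at the anterior pole of larvae."],
     ["apical ganglion", "apical rosette", "apical plate"],
     ["sensory organ", "nervous system", "receptor cell"]),
    (2, "arcuate body", (MAIN, "unpaired midline neuropil"), [("syncerebrum", S)],
     ["It is connected to second order visual neuropils and to postoral neuropils."],
     [],
     ["unpaired midline neuropil", "syncerebrum", "neuropil"]),
    (3, "brain", (CLUS, "neuron"), [("nervous system", S)],
     ["It is the most prominent anterior condensation of neurons and may also "
      "include further types of cells, including glial cells and pigment cells."],
     ["cerebral ganglion", "supraesophageal ganglion"],
     ["neuron", "nervous system", "glial cell"]),
    (4, "central body", (MAIN, "unpaired midline neuropil"), [("central complex", E)],
     ["It is composed of tangential and columnar neurons.",
      "These neurons form horizontal layers and provide a connection to the "
      "lateral accessory lobes and the protocerebral bridge.",
      "Subpopulations of the columnar neurons cross the midline of the "
      "syncerebrum within the central body or before entering the central body."],
     [],
     ["unpaired midline neuropil", "central complex", "neuron",
      "lateral accessory lobe", "protocerebral bridge", "syncerebrum"]),
    (5, "central complex", (CLUS, "neuropil"), [("syncerebrum", S)],
     ["It consists of three interconnected subunits: the unpaired central body, "
      "which is situated in the middle of the neuropil assembly, the unpaired "
      "protocerebral bridge and the paired lateral accessory lobes."],
     [],
     ["neuropil", "syncerebrum", "central body", "protocerebral bridge",
      "lateral accessory lobe"]),
    (6, "commissure", (MAIN, "neurite bundle"), [("nervous system", S)],
     ["It is transversely oriented and the majority of its neurites are axons "
      "of interneurons."],
     [],
     ["neurite bundle", "nervous system", "neurite"]),
    (7, "compound eye", (MAIN, "eye"), [("nervous system", S)],
     ["It consists of several to numerous almost identical components, the ommatidia.",
      "The sensory input of the compound eye is processed by at least two "
      "retinotopic neuropils connected to the syncerebrum."],
     ["facetted eye"],
     ["eye", "nervous system", "ommatidium", "neuropil", "syncerebrum"]),
    (8, "connective", (MAIN, "neurite bundle"), [("nervous system", S)],
     ["It is completely or almost free of somata and interconnects ganglia "
      "longitudinally."],
     [],
     ["neurite bundle", "nervous system", "ganglion"]),
    (9, "eye", (MAIN, "sensory organ"), [("nervous system", S)],
     ["It consists of at least one photoreceptor cell and one separate "
      "pigmented supportive cell.",
      "An eye allows directional access of light to the photosensitive structures."],
     ["photoreceptor", "ocellus"],
     ["sensory organ", "nervous system", "photoreceptor cell"]),
    (10, "ganglion", (CLUS, "neuron"), [("nervous system", S)],
     ["It may include glial cells.",
      "The neurons are arranged in a specific constellation: neuronal somata "
      "are concentrated at the surface, thus forming a cell cortex, and "
      "neurites are concentrated in the centre of the ganglion to form the neuropil.",
      "A ganglion is a distinct unit but several ganglia may be "
      "anterio-posteriorly joined by connectives or transversally by commissures."],
     [],
     ["neuron", "nervous system", "glial cell", "neurite", "neuropil",
      "connective", "commissure"]),
    (11, "ganglion mother cell", (MAIN, "neuronal precursor"), [("nervous system", S)],
     ["It is generated by an asymmetrical division of a neuroblast.",
      "It divides once to produce neurons and/or glial cells."],
     [],
     ["neuronal precursor", "nervous system", "neuroblast", "neuron", "glial cell"]),
    (12, "glial cell", (PRIM, "cell"), [("nervous system", E)],
     ["A glial cell interacts closely with neurons by providing nutrients, "
      "removing the waste products of neuronal metabolism, electrically "
      "insulating the neurons and controlling the passage of substances from "
      "the blood to the neurons.",
      "It also supports, via its cytoskeleton, the structural arrangement of "
      "the cellular components of the nervous tissue."],
     ["neuroglia", "supportive cell"],
     ["nervous system", "neuron"]),
    (13, "globuli cell", (MAIN, "neuron"), [],
     ["It is part of a cluster of other globuli cells.",
      "It possesses a minute amount of cytoplasm and a nucleus containing "
      "condensed chromatin.",
      "The somata of globuli cells are densely packed and easily discernable "
      "from other neighbouring neuronal somata due to their small diameter."],
     [],
     ["neuron"]),
    (14, "lateral accessory lobe", (MAIN, "neuropil"), [("central complex", E)],
     ["A pair of lateral accessory lobes is located slightly posterior to the "
      "central body.",
      "Descending and ascending neurons of the lateral accessory lobes "
      "establish connections between the central complex and the postoral neuropils."],
     ["ventral body", "lateral lobe"],
     ["neuropil", "central complex", "central body", "neuron"]),
    (15, "median eye", (MAIN, "eye"), [("nervous system", S)],
     ["It is connected to a paired or unpaired median anterior neuropil of the "
      "syncerebrum by one or several median eye nerve(s)."],
     ["frontal ocellus", "median ocellus"],
     ["eye", "nervous system", "neuropil", "syncerebrum"]),
    (16, "medullary cord", (MAIN, "nerve cord"), [("nervous system", S)],
     ["It consists of a longitudinally extending central neuropil surrounded "
      "by a cell cortex consisting of neuronal somata distributed along its "
      "entire length.",
      "It may contain glial cells and receptor cells.",
      "A medullary cord is not divided into ganglia and soma-free connectives."],
     ["Markstrang"],
     ["nerve cord", "nervous system", "neuropil", "glial cell", "receptor cell",
      "ganglion", "connective"]),
    (17, "mushroom body", (MAIN, "neuropil"), [("brain", S)],
     ["Mushroom bodies are paired and have a lobed shape.",
      "A mushroom body is composed of dendrites and parallelly arranged axons "
      "made up of thousands of intrinsic neurons of the globuli cell type."],
     ["corpora pedunculata"],
     ["neuropil", "brain", "neuron", "globuli cell"]),
    (18, "nauplius eye", (MAIN, "eye"), [("nervous system", S)],
     ["It consists of a cluster of three or four median eyes that form a "
      "single structural unit but are separated from one another by pigment layers."],
     ["three-partite eye", "four-partite eye"],
     ["eye", "nervous system", "median eye"]),
    (19, "nerve", (MAIN, "neurite bundle"), [("nervous system", S)],
     ["It connects a condensed nervous structure with a given region in the "
      "periphery, i.e., with receptor cells (mechanoreceptors, hygroreceptors, "
      "chemoreceptors, photoreceptors) or effectors (glands, fat body, "
      "muscles) or both."],
     [],
     ["neurite bundle", "nervous system", "receptor cell"]),
    (20, "nerve cord", (CLUS, "neuron"), [("nervous system", S)],
     ["It is the most prominent longitudinally extending condensed part of a "
      "nervous system."],
     [],
     ["neuron", "nervous system"]),
    (21, "nervous system", (CLUS, "neuron"), [],
     ["It comprises all neurons of an organism and may include additional "
      "glial cells.",
      "It may also include accessory cells, which, for example, serve as "
      "supportive structures, stimulus guiding structures, or protective structures."],
     [],
     ["neuron", "glial cell"]),
    (22, "neural tube", (MAIN, "nerve cord"), [("nervous system", S)],
     ["It has a tubular structure and contains a central fluid-filled canal, "
      "the neural canal."],
     ["nerve tube"],
     ["nerve cord", "nervous system"]),
    (23, "neurite", (PRIM, "cell process"), [("neuron", S)],
     ["Neurites are divided into primary neurites, axons, and dendrites."],
     ["nerve fiber", "Nervenfaser", "axis cylinder", "nerve"],
     ["neuron"]),
    (24, "neurite bundle", (CLUS, "neurite"), [("nervous system", E)],
     ["The neurites are arranged in parallel to form a bundle."],
     [],
     ["neurite", "nervous system"]),
    (25, "neuroactive substance", (PRIM, "molecule"), [("nervous system", E)],
     ["It is diffusible and influences the physiological state of neurons by "
      "interacting with a competent receptor."],
     [],
     ["nervous system", "neuron"]),
    (26, "neuroblast", (MAIN, "neuronal precursor"), [("nervous system", S)],
     ["It is comparably large and acts as a stem cell.",
      "It divides asymmetrically and preferentially in one direction only, "
      "giving rise to smaller cells, the ganglion mother cells."],
     [],
     ["neuronal precursor", "nervous system", "ganglion mother cell"]),
    (27, "neuromere", (CLUS, "cell"), [("nervous system", S)],
     ["It consists of all the developing nervous tissue that is part of one of "
      "the several anterior-posterior repetitive units of the nervous system."],
     [],
     ["cell", "nervous system"]),
    (28, "neuron", (PRIM, "cell"), [("nervous system", E)],
     ["It consists of a soma that gives rise to neurites, which conduct "
      "electric excitation in a directed way.",
      "A neuron communicates with other cells via synapses.",
      "Most neurons synthesize and secrete neuroactive substances."],
     ["nerve cell"],
     ["nervous system", "neurite", "synapse", "neuroactive substance"]),
    (29, "neuronal precursor", (PRIM, "cell"), [("nervous system", S)],
     ["It produces either further neuronal precursors or neurons or glial cells."],
     ["neuronal progenitor"],
     ["nervous system", "neuron", "glial cell"]),
    (30, "neuropil", (CLUS, "neurite"), [("nervous system", S)],
     ["It forms a network of dendrites and axons where synapses are present "
      "and in which neuronal somata do not occur."],
     [],
     ["neurite", "nervous system", "synapse"]),
    (31, "olfactory glomerulus", (MAIN, "neuropil"), [("nervous system", S)],
     ["An olfactory glomerulus is a clearly demarcated, dense neuropil in "
      "which olfactory receptor neurons terminate and form the first synapses "
      "of the olfactory pathway."],
     [],
     ["neuropil", "nervous system", "neuron", "synapse"]),
    (32, "ommatidium", (MAIN, "eye"), [("compound eye", E)],
     ["It is the smallest morphological and functional unit of the compound eye.",
      "It consists of a usually limited and often constant number of "
      "rhabdomeric photoreceptor cells, cornea-secreting epithelial cells, and "
      "interommatidial pigment cells, and may additionally contain crystalline "
      "cone cells."],
     [],
     ["eye", "compound eye", "photoreceptor cell"]),
    (33, "orthogon", (CLUS, "neuron"), [("nervous system", S)],
     ["It consists of at least two pairs of longitudinal neurite bundles, "
      "which are connected at regular intervals by transverse neurite bundles "
      "running at right angles to them (i.e., orthogonally).",
      "The transverse bundles may form a closed circle (circular bundles or "
      "ring commissures), or at least connect all the longitudinal bundles present.",
      "The thickness of the longitudinal neurite bundles can vary, usually "
      "with the ventral one being thicker than the others.",
      "An orthogon is not differentiated into ganglia linked by connectives."],
     [],
     ["neuron", "nervous system", "neurite bundle", "ganglion", "connective"]),
    (34, "photoreceptor cell", (MAIN, "receptor cell"), [("sensory organ", S)],
     ["It contains photosensitive pigments.",
      "The adequate stimulus is light."],
     ["photoreceptor", "photosensitive cell"],
     ["receptor cell", "sensory organ"]),
    (35, "pioneer neuron", (MAIN, "neuron"), [("nervous system", S)],
     ["It appears early in development, often exists transiently, and is "
      "involved in setting up the scaffold of the developing nervous system.",
      "The neurites of the pioneer neurons serve as pathways for the neurites "
      "of neurons, which develop later."],
     [],
     ["neuron", "nervous system", "neurite"]),
    (36, "plexus", (CLUS, "neuron"), [("nervous system", S)],
     ["It consists of neurites or neurite bundles that are arranged in a "
      "planar reticular pattern.",
      "The somata of the neurons are considered to be part of the plexus."],
     ["epithelial nervous system", "diffuse nervous system", "nerve net"],
     ["neuron", "nervous system", "neurite", "neurite bundle"]),
    (37, "protocerebral bridge", (MAIN, "neuropil"), [("central complex", E)],
     ["Within the protocerebral bridge, neurites of columnar neurons form "
      "their first collaterals before entering the central body.",
      "The somata of these neurons lie adjacent to and dorsal of the "
      "protocerebral bridge."],
     [],
     ["neuropil", "central complex", "neurite", "neuron", "central body"]),
    (38, "receptor cell", (MAIN, "neuron"), [("nervous system", E)],
     ["In a signal transduction chain, it is the first neuron that converts "
      "an adequate stimulus into an electric signal."],
     ["sensory neuron", "sensory cell", "receptor"],
     ["neuron", "nervous system"]),
    (39, "rope-ladder-like nervous system", (MAIN, "nerve cord"), [("nervous system", S)],
     ["It consists of a series of ganglia joined by commissures and connectives.",
      "The ganglia are arranged in an anterior-posterior sequence.",
      "The bilaterally arranged pairs of ganglia are transversally joined by "
      "at least one commissure.",
      "Longitudinally, the ganglia are joined by exactly one connective per side.",
      "Segmental nerves exit the rope-ladder-like nervous system."],
     ["ladder-like nervous system"],
     ["nerve cord", "nervous system", "ganglion", "commissure", "connective",
      "nerve"]),
    (40, "sensory organ", (CLUS, "cell"), [("nervous system", S)],
     ["It consists of receptor cells, which form a multicellular unit that "
      "may include accessory cells, which serve as supportive structures, "
      "stimulus-guiding structures or protective structures."],
     ["sense organ"],
     ["cell", "nervous system"]),
    (41, "synapse", (PRIM, "cell-to-cell junction"), [("nervous system", E)],
     ["It consists of pre- and postsynaptic components.",
      "It is situated between a neuron and another cell (e.g., neuron, muscle "
      "cell, gland cell) and mediates the transduction of an electric signal "
      "between them."],
     [],
     ["nervous system", "neuron"]),
    (42, "syncerebrum", (MAIN, "brain"), [("nervous system", S)],
     ["It is formed by the fusion or close association of several neuromeres."],
     [],
     ["brain", "nervous system", "neuromere"]),
    (43, "tetraneurion", (CLUS, "neuron"), [("nervous system", S)],
     ["It consists of two prominent pairs of longitudinal neurite bundles: "
      "one inner, ventral pair and one more dorsally situated lateral pair.",
      "It may include ganglia."],
     ["tetraneural nervous system"],
     ["neuron", "nervous system", "neurite bundle", "ganglion"]),
    (44, "tract", (MAIN, "neurite bundle"), [("brain", S), ("ganglion", S)],
     ["It connects different neuropils with each other."],
     [],
     ["neurite bundle", "brain", "ganglion", "neuropil"]),
    (45, "trochal neurite", (MAIN, "neurite"), [("neuron", S)],
     ["It underlies a ciliated trochus."],
     [],
     ["neurite", "neuron"]),
    (46, "trochal neurite bundle", (MAIN, "neurite bundle"), [("nervous system", S)],
     ["It underlies a ciliated trochus."],
     ["prototroch nerve ring", "telotroch nerve ring", "prototroch nerve",
      "telotroch nerve", "trochus nerve"],
     ["neurite bundle", "nervous system"]),
    (47, "unpaired midline neuropil", (MAIN, "neuropil"), [("brain", S)],
     ["It occurs as an individual neuropil, spanning the midsagittal plane of "
      "the brain."],
     [],
     ["neuropil", "brain"]),
]

# register rows of the 47 main entries (defining number = own entry id)
MAIN_REGISTER = {
    "apical organ": [1, 10],
    "arcuate body": [2, 4, 47],
    "brain": [1, 2, 3, 9, 10, 12, 13, 14, 17, 18, 19, 22, 26, 37, 40, 42, 44, 47],
    "central body": [2, 4, 5, 14, 30, 37, 47],
    "central complex": [4, 5, 14, 37],
    "commissure": [6, 10, 39, 42],
    "compound eye": [7, 9, 32, 42],
    "connective": [3, 8, 10, 16, 27, 33, 39],
    "eye": [7, 9, 15, 18, 32, 34, 40, 42],
    "ganglion": [1, 3, 6, 8, 10, 12, 14, 16, 19, 20, 21, 22, 26, 27, 28, 31, 33,
                 39, 42, 43, 44],
    "ganglion mother cell": [11, 26, 35],
    "glial cell": [3, 10, 11, 12, 16, 18, 21, 29, 30],
    "globuli cell": [13, 17],
    "lateral accessory lobe": [4, 5, 14],
    "median eye": [9, 15, 18, 42],
    "medullary cord": [8, 10, 16, 20],
    "mushroom body": [13, 17, 42],
    "nauplius eye": [15, 18],
    "nerve": [3, 10, 18, 19, 23],
    "nerve cord": [3, 16, 20, 22, 24, 39, 46],
    "nervous system": [1, 3, 6, 7, 8, 9, 10, 11, 12, 15, 16, 18, 19, 20, 21, 22,
                       23, 24, 25, 26, 27, 28, 29, 30, 31, 33, 35, 36, 38, 39,
                       40, 41, 42, 43, 46],
    "neural tube": [10, 21, 22],
    "neurite": [3, 6, 8, 10, 12, 21, 23, 24, 28, 30, 35, 36, 37, 42, 45, 46],
    "neurite bundle": [6, 8, 12, 19, 20, 21, 24, 33, 36, 39, 43, 44, 46],
    "neuroactive substance": [25, 28, 41],
    "neuroblast": [11, 26, 29, 35],
    "neuromere": [6, 27, 42],
    "neuron": [3, 4, 10, 11, 12, 13, 14, 17, 20, 21, 23, 25, 28, 29, 31, 33, 35,
               36, 37, 38, 41, 42, 43, 45],
    "neuronal precursor": [11, 26, 29],
    "neuropil": [2, 3, 4, 5, 6, 7, 10, 13, 14, 15, 16, 17, 28, 30, 31, 37, 42,
                 44, 47],
    "olfactory glomerulus": [30, 31, 42],
    "ommatidium": [7, 9, 15, 32],
    "orthogon": [6, 33, 36],
    "photoreceptor cell": [9, 32, 34, 38],
    "pioneer neuron": [26, 35],
    "plexus": [23, 33, 36],
    "protocerebral bridge": [4, 5, 37, 47],
    "receptor cell": [1, 16, 19, 34, 36, 38, 40],
    "rope-ladder-like nervous system": [6, 10, 39],
    "sensory organ": [1, 9, 34, 38, 40],
    "synapse": [10, 28, 30, 31, 36, 41, 44],
    "syncerebrum": [2, 3, 4, 5, 7, 15, 42],
    "tetraneurion": [1, 43],
    "tract": [3, 6, 10, 19, 30, 44],
    "trochal neurite": [45, 46],
    "trochal neurite bundle": [45, 46],
    "unpaired midline neuropil": [2, 4, 37, 42, 47],
}

# side-entry rows of the register (terms used without their own definition)
SIDE_REGISTER = {
    "accessory cilium": [34],
    "adult eye": [9],
    "afferent": [15, 19],
    "apical ganglion": [1, 10],
    "apical plate": [1],
    "apical rosette": [1],
    "archicerebrum": [42],
    "axis cylinder": [23],
    "axon": [3, 6, 8, 10, 12, 17, 18, 19, 23, 28, 30, 38, 44],
    "basiepidermal plexus": [36],
    "biogenic amine": [25],
    "bipolar cell": [38],
    "bipolar neuron": [28, 38],
    "calyx": [17],
    "cell cortex": [3, 10, 16, 30],
    "central nervous system": [10, 19, 21, 42],
    "cerebral commissure": [1, 42],
    "cerebral eye": [7, 9],
    "cerebral ganglion": [3, 10],
    "chemical synapse": [36, 41],
    "chemoreception": [38],
    "ciliary photoreceptor cell": [32, 34],
    "collar receptor cell": [38],
    "commissural brain": [3],
    "compound brain": [3, 42],
    "converse eye": [9],
    "cornea": [9, 32, 34],
    "corneageneous cell": [32],
    "cornea-secreting epithelial cell": [32],
    "corpora pedunculata": [17],
    "crystalline cone": [32],
    "cycloneuralian brain": [3],
    "dendrite": [10, 17, 23, 28, 30, 38],
    "deutocerebrum": [31, 42, 44],
    "diffuse nervous system": [36],
    "dioptric apparatus": [32],
    "effector": [19, 40],
    "efferent": [19],
    "electrical synapse": [36, 41],
    "electroreception": [38],
    "epidermal plexus": [36],
    "epithelial nervous system": [36],
    "everse eye": [9, 18],
    "extracerebral eye": [9],
    "extraocular photoreceptor": [34],
    "extrinsic neuron": [28],
    "facetted eye": [7],
    "flask-shaped receptor cell": [1, 38],
    "four-partite eye": [15, 18],
    "free nerve ending": [38],
    "frontal eye": [18],
    "frontal ocellus": [15],
    "frontal organ": [18],
    "gastrodermal plexus": [36],
    "gastrotroch": [46],
    "hemiellipsoid body": [13, 44],
    "hemiganglion": [6, 10],
    "hygroreception": [38],
    "individually identifiable neuron": [28],
    "interneuron": [6, 8, 10, 28, 30, 36, 44],
    "interommatidial pigment cell": [7, 32],
    "intraepidermal plexus": [36],
    "intrinsic neuron": [17, 28],
    "inverse eye": [9, 18],
    "iris": [9],
    "kenyon cells": [13, 17],
    "ladder-like nervous system": [39],
    "larval eye": [9],
    "lateral eye": [9, 15, 32, 42],
    "lateral lobe": [14],
    "lateral ocellus": [7, 9, 15],
    "lens": [9, 32, 40],
    "magnetoreception": [38],
    "markstrang": [16],
    "mechanoreception": [38],
    "median eye nerve": [15],
    "median ocellus": [15],
    "motoneuron": [19, 28, 36],
    "multipolar neuron": [10, 28],
    "nerve cell": [23, 28],
    "nerve fiber": [23],
    "nervenfaser": [23],
    "nerve net": [36],
    "nerve tube": [22],
    "nervous tissue": [12, 21, 22, 27],
    "neural canal": [22],
    "neural cord": [22],
    "neurenteric canal": [22],
    "neurilemma": [12],
    "neuroglia": [12],
    "neuronal progenitor": [29],
    "neuropeptide": [25],
    "neuropore": [22],
    "neurotroch": [46],
    "neurulation": [22],
    "non-neuronal sensory cell": [38],
    "ocellus": [7, 9, 15],
    "pedunculus": [17],
    "perikaryon": [28],
    "perilemma": [12],
    "perineurium": [12],
    "peripheral nervous system": [21],
    "phaosome": [34],
    "photoreception": [9, 34, 38],
    "photoreceptor": [9, 15, 19, 34],
    "photosensitive cell": [34],
    "phototaxis": [9],
    "pigment cell": [3, 9, 18, 32, 34],
    "pigment-cup eye": [9],
    "pigmented supportive cell": [9, 34],
    "primary neurite": [10, 23, 28],
    "primary pigment cell": [32],
    "prosocerebrum": [42],
    "protocerebrum": [5, 15, 18, 31, 42, 44],
    "prototroch nerve": [46],
    "prototroch nerve ring": [46],
    "prototype eye": [9],
    "pseudounipolar neuron": [28],
    "receptor": [21, 25, 38],
    "retina": [9, 34],
    "retinula(r) cell": [32],
    "rhabdom": [32],
    "rhabdomeric photoreceptor cell": [32, 34],
    "rhopalium": [3, 9, 40],
    "ring commissure": [6, 33],
    "secondary sensory cell": [38],
    "sense organ": [40],
    "sensory cell": [18, 38],
    "sensory epithelial cell": [38],
    "sensory neuron": [38],
    "septate junction": [34],
    "sheath": [12],
    "soma": [3, 8, 10, 13, 16, 17, 19, 23, 27, 28, 30, 36, 37, 38],
    "stemmata": [7, 9, 15],
    "subepidermal plexus": [36],
    "supportive cell": [9, 12, 34],
    "supraesophageal ganglion": [3],
    "tapetum": [9, 18],
    "telotroch nerve": [46],
    "telotroch nerve ring": [46],
    "tetraneural nervous system": [43],
    "tetraneury": [43],
    "thermoreception": [38],
    "three-partite eye": [18],
    "tritocerebrum": [3, 42],
    "trochus nerve": [46],
    "unipolar neuron": [10, 23, 28],
    "unpigmented ocellus": [9, 34],
    "ventral body": [14],
    "ventral nerve cord": [20, 46],
    "vitreous body": [9],
    "zonula adhaerens": [34],
}

PRIMITIVES = frozenset({"cell", "molecule", "cell process", "cell-to-cell junction"})


def build_kb() -> KnowledgeBase:
    terms = [
        TermEntry(
            entry_id=eid,
            label=label,
            genus=ParentRef(*genus),
            parts=tuple(PartStatement(w, q) for w, q in parts),
            differentia=tuple(diff),
            discouraged=tuple(disc),
            def_xrefs=frozenset(xrefs),
        )
        for eid, label, genus, parts, diff, disc, xrefs in ENTRIES
    ]
    sides = [SideEntry(label=label) for label in SIDE_REGISTER]
    register = [
        RegisterRow(label, frozenset(entries), defining_entry=eid)
        for label, entries in MAIN_REGISTER.items()
        for eid in [next(t.entry_id for t in terms if t.label == label)]
    ] + [
        RegisterRow(label, frozenset(entries))
        for label, entries in SIDE_REGISTER.items()
    ]
    return KnowledgeBase.create(
        terms=terms,
        sides=sides,
        primitives=PRIMITIVES,
        register=sorted(register, key=lambda r: r.label),
        provenance=Provenance(version="1", checksum=""),
    )


def main() -> None:
    kb = build_kb()
    text = write_corpus(kb)
    reparsed = parse_corpus(text)
    assert reparsed == kb, "round-trip mismatch"
    assert write_corpus(reparsed) == text, "canonical form not a fixed point"
    out = Path(__file__).resolve().parents[1] / "src/neurogloss/data/glossary.inc"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(text, encoding="utf-8")
    print(f"wrote {out} ({len(text)} bytes, {len(kb.terms)} terms, "
          f"{len(kb.sides)} sides, {len(kb.register)} register rows)")


if __name__ == "__main__":
    main()
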