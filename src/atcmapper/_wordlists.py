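"""Static Dutch word lists used by the pre-processing step.

The stop-word list is a compact curated set of common Dutch function words
(articles, pronouns, prepositions, auxiliaries) of the kind shipped by NLP
toolkits; the filler, company and application-form lists are seeded from the
categories observed in questionnaire answers and are user-extensible through
:class:`atcmapper.preprocess.PreprocessConfig`.
"""

# common Dutch function words
DUTCH_STOP_WORDS = frozenset(
    """
    de het een en of maar want dus als dan toch ook nog al wel niet geen
    ik je jij u hij zij ze we wij jullie men me mij jou hem haar ons hun
    mijn jouw uw zijn onze deze die dit dat welke wat wie iets niets alles
    er hier daar waar ergens nergens overal
    aan af bij in op uit van voor naar met zonder over onder tussen door
    tegen tot sinds binnen buiten langs om rond per
    is ben bent was waren wordt worden werd werden heb hebt heeft hebben
    had hadden kan kunnen kon konden moet moeten mag mogen wil willen zal
    zullen zou zouden doe doet doen deed ga gaat gaan ging
    te zo nu dan ja nee heel erg zeer veel weinig meer minder soms vaak
    altijd nooit weer eens even maal keer
    """.split()
)

# domain-specific filler words and phrases seen in medication answers
FILLER_TERMS = (
    "elke dag",
    "iedere dag",
    "per dag",
    "dagelijks",
    "zo nodig",
    "zonodig",
    "indien nodig",
    "plus",
    "forte",
    "retard",
    "merk",
    "merkloos",
    "eigen merk",
    "weet niet",
    "geen idee",
    "niet van toepassing",
    "nvt",
    "tablet per dag",
    "x per dag",
    "keer per dag",
    "1x",
    "2x",
    "3x",
)

# most common pharmaceutical company names appearing after drug names
COMPANY_NAMES = (
    "sandoz",
    "teva",
    "mylan",
    "accord",
    "aurobindo",
    "pfizer",
    "bayer",
    "ratiopharm",
    "centrafarm",
    "pch",
    "apotex",
    "kruidvat",
    "etos",
    "hema",
)

# multi-word phrases that must never be split apart
EXCEPTION_PHRASES = (
    "vitamine c",
    "vitamin c",
    "vitamine d",
    "vitamine d3",
    "vitamine b12",
    "vitamine b6",
    "sint janskruid",
    "st janskruid",
)

# application-form words kept attached to the preceding drug name:
# the form can decide the ATC code (systemic vs topical vs nasal)
APPLICATION_FORMS = (
    "tablet",
    "tabletten",
    "dispertablet",
    "bruistablet",
    "kauwtablet",
    "zetpil",
    "capsule",
    "creme",
    "zalf",
    "gel",
    "spray",
    "neusspray",
    "oogdruppels",
    "oordruppels",
    "druppels",
    "inhalator",
    "pleister",
    "siroop",
    "drank",
    "injectie",
)

EMPTY_ANSWER_CODES = ("8888", "9999")
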