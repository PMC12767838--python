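"""Small built-in rules and networks used throughout tests and examples.

The two named rules come from a published Boolean model of the Fanconi
anemia / DNA-repair pathway and are reproduced here from their printed
logical expressions:

* FANCM = CHKREC AND (NOT ICL) -- expressed only when CHKREC is active
  and the ICL signal is silenced;
* ADD, a five-input rule whose inputs, in fixed alphabetical order
  x1..x5 = ADD, FAN1, MUS81, PCNATLS, XPF, read
  NOT FAN1 AND (MUS81 AND PCNATLS OR MUS81 AND ADD OR XPF).

The alphabetical input order matters: all worked-example numbers (layer
order, effectiveness values, polynomial terms) are stated in it, so the
builders hard-code it rather than relying on appearance order in the
expression text.
"""

from __future__ import annotations

from .core import DiscreteFunction
from .network import LogicNetwork, parse_expressions

__all__ = [
    "fancm_rule",
    "add_rule",
    "ADD_INPUTS",
    "fancm_network",
    "repressilator",
    "pruning_motif",
]

ADD_INPUTS = ("ADD", "FAN1", "MUS81", "PCNATLS", "XPF")


def fancm_rule() -> DiscreteFunction:
    """2-input rule CHKREC AND (NOT ICL)."""
    return DiscreteFunction.from_callable(
        2, 2, lambda x: x[0] & (1 - x[1]), ("CHKREC", "ICL"))


def add_rule() -> DiscreteFunction:
    """The 5-input ADD rule over (ADD, FAN1, MUS81, PCNATLS, XPF)."""
    def fn(x):
        add, fan1, mus81, pcnatls, xpf = x
        return (1 - fan1) & ((mus81 & pcnatls) | (mus81 & add) | xpf)

    return DiscreteFunction.from_callable(5, 2, fn, ADD_INPUTS)


def fancm_network() -> LogicNetwork:
    """One regulated gene plus its two external inputs."""
    return parse_expressions("FANCM = CHKREC and (not ICL)\n")


def repressilator() -> LogicNetwork:
    """Three genes in a cycle of negations: a canonical oscillator."""
    return parse_expressions(
        "A = not C\n"
        "B = not A\n"
        "C = not B\n")


def pruning_motif() -> LogicNetwork:
    """Five genes: a 2-cycle feeding a relay that feeds two terminals.

    Gene1 and Gene2 form the relevant part; Gene3 regulates only the
    terminals Gene4 and Gene5 and is itself a relay.
    """
    return parse_expressions(
        "Gene1 = Gene2\n"
        "Gene2 = not Gene1\n"
        "Gene3 = Gene1 and Gene2\n"
        "Gene4 = Gene3\n"
        "Gene5 = not Gene3\n")
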