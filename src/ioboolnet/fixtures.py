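"""Shipped biological and toy models plus their interconnection schemes.

The catalog contains:

* ``example1_A`` -- two-variable cascade u -> x1 -> x2 (SISO);
* ``example2_B`` -- one-variable inverter y1+ = !v (SISO);
* ``example4_A``/``example4_B`` -- synthetic two-variable SISO modules
  constructed to exhibit a two-block / all-singleton meet-partition
  structure (see the data files);
* ``clock7`` -- seven-variable circadian clock with mitotic shutdown input;
* ``cellsize8`` -- eight-variable budding-yeast cell-size module;
* ``mammal_cc10`` -- ten-variable mammalian cell-cycle module (BMAL input);
* ``yeast_cc11`` -- eleven-variable budding-yeast cell-cycle module (START
  input; default output flags M phase).

Interconnection schemes: ``mammal`` couples cell cycle and clock
(u = BMAL, v = Cdc20 & CycB); the yeast schemes couple cell cycle and cell
size with u = Cln3F and v indicating M phase (Swi5 & Cdc20), S phase
(Clb5) or G1 phase (Cdh1 & Sic1).
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, Tuple

from .core import IOBooleanModule, parse_module
from .expr import parse_expr
from .interconnect import InterconnectionScheme, two_module_scheme

#: name -> (file, (n, p, q), provenance note)
CATALOG: Dict[str, Tuple[str, Tuple[int, int, int], str]] = {
    "example1_A": ("example1_A.bnetio", (2, 1, 1),
                   "two-variable SISO cascade"),
    "example2_B": ("example2_B.bnetio", (1, 1, 1),
                   "one-variable SISO inverter"),
    "example4_A": ("example4_A_synthetic.bnetio", (2, 1, 1),
                   "synthetic module with a two-block meet partition"),
    "example4_B": ("example4_B_synthetic.bnetio", (2, 1, 1),
                   "synthetic module with an all-singleton meet partition"),
    "clock7": ("clock7.bnetio", (7, 1, 1),
               "circadian clock with transcription-shutdown input"),
    "cellsize8": ("cellsize8.bnetio", (8, 1, 1),
                  "cell-size / START module (Ydj1 chaperone competition)"),
    "mammal_cc10": ("mammal_cc10.bnetio", (10, 1, 1),
                    "mammalian cell cycle (Faure et al. rules, BMAL input)"),
    "yeast_cc11": ("yeast_cc11.bnetio", (11, 1, 1),
                   "budding-yeast cell cycle (Li et al. rules, START input)"),
}

SCHEME_NAMES = ("mammal", "yeast_M", "yeast_S", "yeast_G1")

#: cell-cycle-phase output used as the growth-rate indicator, per scheme
_YEAST_OUTPUTS = {
    "yeast_M": ("mphase", "Swi5 & Cdc20"),
    "yeast_S": ("sphase", "Clb5"),
    "yeast_G1": ("g1phase", "Cdh1 & Sic1"),
}


def fixture_text(name: str) -> str:
    if name not in CATALOG:
        raise KeyError(f"unknown fixture {name!r}; "
                       f"known: {sorted(CATALOG)}")
    fname = CATALOG[name][0]
    return (resources.files("ioboolnet") / "data" / fname).read_text()


def load_fixture(name: str) -> IOBooleanModule:
    """Load and validate a catalog module."""
    module = parse_module(fixture_text(name))
    n, p, q = CATALOG[name][1]
    if (module.n, module.p, module.q) != (n, p, q):
        raise AssertionError(
            f"fixture {name} has dimensions "
            f"{(module.n, module.p, module.q)}, expected {(n, p, q)}")
    return module


def with_outputs(module: IOBooleanModule,
                 outputs: Tuple[Tuple[str, str], ...]) -> IOBooleanModule:
    """Copy of a module with the output rules replaced (name, expression)."""
    return IOBooleanModule(
        name=module.name,
        variable_names=module.variable_names,
        input_names=module.input_names,
        update_rules=module.update_rules,
        output_names=tuple(n for n, _ in outputs),
        output_rules=tuple(parse_expr(e) for _, e in outputs),
    )


def scheme(name: str) -> InterconnectionScheme:
    """A named two-module interconnection scheme from the catalog."""
    if name == "mammal":
        return two_module_scheme(load_fixture("mammal_cc10"),
                                 load_fixture("clock7"))
    if name in _YEAST_OUTPUTS:
        cc = load_fixture("yeast_cc11")
        cc = with_outputs(cc, (_YEAST_OUTPUTS[name],))
        return two_module_scheme(cc, load_fixture("cellsize8"))
    if name == "example":
        return two_module_scheme(load_fixture("example1_A"),
                                 load_fixture("example2_B"))
    if name == "example4":
        return two_module_scheme(load_fixture("example4_A"),
                                 load_fixture("example4_B"))
    raise KeyError(f"unknown scheme {name!r}; known: "
                   f"{SCHEME_NAMES + ('example', 'example4')}")
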