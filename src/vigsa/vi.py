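"""Vegetation-index expressions: parsing, evaluation and the built-in registry.

Index formulas are plain-text arithmetic over band-role symbols (BLUE,
GREEN, RED, RedEdge, NIR, SWIR) and explicit wavelength terms ``rho(λ)``,
with ``+ - * / ^``, ``sqrt`` and ``abs``.  Role symbols resolve through a
sensor's role map (or nominal wavelengths on a native grid); ``rho(λ)``
resolves to the nearest grid point or band center.

Division guards: a denominator smaller than 1e-9 in magnitude yields NaN
for that simulation, which the estimator layer excludes row-wise rather
than fabricating an index value at degenerate reflectances.

The shipped registry covers published indices targeting leaf chlorophyll
content (LCC), leaf water content (LWC) and leaf area index (LAI), with the
sensors each index is conventionally applied to.  The target tags are
organizational, not validated claims.  Formulas whose typeset sources are
ambiguous are shipped in the canonical form of their original publications,
with the ambiguity noted in ``notes``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .sensors import (
    DEFAULT_ROLE_WAVELENGTHS,
    ROLES,
    BandView,
    Sensor,
    get_sensor,
    nearest_band_value,
)

__all__ = [
    "VIDefinition",
    "parse_vi_expression",
    "serialize_expression",
    "evaluate_vi",
    "builtin_registry",
    "all_indices",
    "get_index",
    "NativeGridView",
]

DENOM_GUARD = 1e-9

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>\d+\.\d*|\.\d+|\d+)|(?P<name>[A-Za-z_][A-Za-z_0-9:]*)"
    r"|(?P<op>[-+*/^(),]))"
)

_FUNCS = ("sqrt", "abs", "rho")


def _tokenize(text: str):
    pos = 0
    tokens = []
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            raise SyntaxError(f"unexpected character at position {pos}: {text[pos]!r}")
        if m.group("num") is not None:
            tokens.append(("num", float(m.group("num")), pos))
        elif m.group("name") is not None:
            tokens.append(("name", m.group("name"), pos))
        else:
            tokens.append(("op", m.group("op"), pos))
        pos = m.end()
    tokens.append(("end", None, len(text)))
    return tokens


class _Parser:
    """Recursive-descent parser producing nested tuples:
    ("num", x) | ("role", name) | ("rho", λ) | ("call", fn, arg)
    | ("neg", a) | (op, a, b) for op in + - * / ^ ."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.tokens[self.i]

    def take(self, kind=None, value=None):
        tok = self.tokens[self.i]
        if kind is not None and tok[0] != kind:
            raise SyntaxError(f"expected {value or kind} at position {tok[2]}")
        if value is not None and tok[1] != value:
            raise SyntaxError(f"expected {value!r} at position {tok[2]}")
        self.i += 1
        return tok

    def parse(self):
        node = self.expr()
        tok = self.peek()
        if tok[0] != "end":
            raise SyntaxError(f"unexpected token at position {tok[2]}")
        return node

    def expr(self):
        node = self.term()
        while self.peek()[:2] in (("op", "+"), ("op", "-")):
            op = self.take()[1]
            node = (op, node, self.term())
        return node

    def term(self):
        node = self.factor()
        while self.peek()[:2] in (("op", "*"), ("op", "/")):
            op = self.take()[1]
            node = (op, node, self.factor())
        return node

    def factor(self):
        node = self.unary()
        if self.peek()[:2] == ("op", "^"):
            self.take()
            node = ("^", node, self.factor())  # right-associative
        return node

    def unary(self):
        if self.peek()[:2] == ("op", "-"):
            self.take()
            return ("neg", self.unary())
        return self.primary()

    def primary(self):
        kind, value, pos = self.peek()
        if kind == "num":
            self.take()
            return ("num", value)
        if kind == "op" and value == "(":
            self.take()
            node = self.expr()
            self.take("op", ")")
            return node
        if kind == "name":
            self.take()
            if value == "rho":
                self.take("op", "(")
                wl = self.take("num")[1]
                self.take("op", ")")
                return ("rho", wl)
            if value in ("sqrt", "abs"):
                self.take("op", "(")
                arg = self.expr()
                self.take("op", ")")
                return ("call", value, arg)
            for role in ROLES:
                if value.lower() == role.lower():
                    return ("role", role)
            raise SyntaxError(f"unknown symbol {value!r} at position {pos}")
        raise SyntaxError(f"unexpected token at position {pos}")


def parse_vi_expression(text: str):
    """Parse an index formula into an expression tree (nested tuples)."""
    if not text or not text.strip():
        raise SyntaxError("empty expression")
    return _Parser(text).parse()


def serialize_expression(node) -> str:
    """Deterministic text form; round-trips through the parser."""
    kind = node[0]
    if kind == "num":
        v = node[1]
        return str(int(v)) if float(v).is_integer() else repr(v)
    if kind == "role":
        return node[1]
    if kind == "rho":
        return f"rho({serialize_expression(('num', node[1]))})"
    if kind == "call":
        return f"{node[1]}({serialize_expression(node[2])})"
    if kind == "neg":
        return f"(-{serialize_expression(node[1])})"
    a, b = serialize_expression(node[1]), serialize_expression(node[2])
    return f"({a}{kind}{b})"


def expression_symbols(node, roles=None, wavelengths=None):
    """Collect the role symbols and rho wavelengths an expression uses."""
    roles = set() if roles is None else roles
    wavelengths = set() if wavelengths is None else wavelengths
    kind = node[0]
    if kind == "role":
        roles.add(node[1])
    elif kind == "rho":
        wavelengths.add(node[1])
    elif kind in ("neg",):
        expression_symbols(node[1], roles, wavelengths)
    elif kind == "call":
        expression_symbols(node[2], roles, wavelengths)
    elif kind in "+-*/^":
        expression_symbols(node[1], roles, wavelengths)
        expression_symbols(node[2], roles, wavelengths)
    return roles, wavelengths


class NativeGridView:
    """Role/wavelength resolver over spectra on a continuous wavelength grid.

    Role symbols resolve through a role -> wavelength mapping (nominal
    defaults when none is given)."""

    def __init__(self, wavelengths, values, role_wavelengths=None):
        self.wavelengths = np.asarray(wavelengths, dtype=float)
        self.values = np.atleast_2d(np.asarray(values, dtype=float))
        self.role_wavelengths = dict(role_wavelengths or DEFAULT_ROLE_WAVELENGTHS)

    def role(self, role: str) -> np.ndarray:
        if role not in self.role_wavelengths:
            raise KeyError(f"no wavelength assigned to role {role}")
        return self.rho(self.role_wavelengths[role])

    def rho(self, wavelength: float) -> np.ndarray:
        return nearest_band_value(self.wavelengths, self.values, wavelength)


def _eval(node, view) -> np.ndarray:
    kind = node[0]
    if kind == "num":
        return node[1]
    if kind == "role":
        return view.role(node[1])
    if kind == "rho":
        return view.rho(node[1])
    if kind == "neg":
        return -_eval(node[1], view)
    if kind == "call":
        arg = _eval(node[2], view)
        if node[1] == "abs":
            return np.abs(arg)
        with np.errstate(invalid="ignore"):
            return np.where(np.asarray(arg) >= 0, np.sqrt(np.abs(arg)), np.nan)
    a = _eval(node[1], view)
    b = _eval(node[2], view)
    if kind == "+":
        return a + b
    if kind == "-":
        return a - b
    if kind == "*":
        return a * b
    if kind == "/":
        b = np.asarray(b, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(np.abs(b) < DENOM_GUARD, np.nan, a / b)
    if kind == "^":
        with np.errstate(invalid="ignore"):
            return np.asarray(a, dtype=float) ** b
    raise ValueError(f"unknown node {kind!r}")


@dataclass(frozen=True)
class VIDefinition:
    """A named vegetation index.

    ``declared_sensors`` lists the sensors the index is conventionally
    applied to; actual availability additionally requires every referenced
    band to resolve on the sensor (see :func:`builtin_registry`).
    """

    name: str
    abbreviation: str
    expression: str
    target_variable: str  # LCC | LWC | LAI
    declared_sensors: tuple[str, ...] = ()
    notes: str = ""
    _tree: tuple = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_tree", parse_vi_expression(self.expression))

    @property
    def tree(self):
        return self._tree

    def symbols(self):
        return expression_symbols(self.tree)


def evaluate_vi(definition: VIDefinition, view) -> np.ndarray:
    """Evaluate an index over a simulation set.

    ``view`` is a :class:`~vigsa.sensors.BandView` (sensor bands) or
    :class:`NativeGridView` (continuous grid).  Returns one value per
    simulation; NaN flags simulations with guarded denominators.
    """
    return np.asarray(_eval(definition.tree, view), dtype=float)


def sensor_supports(definition: VIDefinition, sensor: Sensor) -> bool:
    """True when every symbol in the index resolves on the sensor."""
    roles, wavelengths = definition.symbols()
    if any(r not in sensor.roles for r in roles):
        return False
    centers = sensor.centers
    return all(np.min(np.abs(centers - wl)) <= 100.0 for wl in wavelengths)


# ---------------------------------------------------------------------------
# built-in registry
# ---------------------------------------------------------------------------

_BROADBAND = ("Landsat8", "MODIS", "Sentinel2", "Sentinel3")
_ALL = _BROADBAND + ("EnMAP",)

_NDVI = "(NIR-RED)/(NIR+RED)"

_DEFS = [
    # --- LCC ---
    ("Chlorophyll vegetation index", "CVI", "NIR*RED/(GREEN^2)", "LCC", _ALL, ""),
    ("Chlorophyll index green", "CIgreen", "NIR/GREEN-1", "LCC", _ALL, ""),
    ("Green leaf index", "GLI",
     "(2*GREEN-RED-BLUE)/(2*GREEN+RED+BLUE)", "LCC", _ALL, ""),
    ("Green NDVI", "GNDVI", "(NIR-GREEN)/(NIR+GREEN)", "LCC", _ALL, ""),
    ("Green ratio vegetation index", "GRVI", "NIR/GREEN", "LCC", _ALL, ""),
    ("Simple ratio 550/800", "SR:550/800", "rho(550)/rho(800)", "LCC", _ALL,
     "shipped as printed (green over NIR); some sources invert the ratio"),
    ("Chlorophyll index red-edge", "CIrededge", "NIR/RedEdge-1", "LCC",
     ("Sentinel2", "Sentinel3", "EnMAP"), ""),
    ("Chlorophyll red-edge", "Chlrededge", "RedEdge/RED-1", "LCC",
     ("EnMAP",), "typeset ambiguously in sources; ratio-minus-one form"),
    ("Double difference index", "DD",
     "(rho(749)-rho(720))-(rho(701)-rho(672))", "LCC", ("EnMAP",), ""),
    ("Double peak index", "DPI", "rho(698)*rho(710)/(rho(697)^2)", "LCC",
     ("EnMAP",), "product form of the original publication"),
    ("Green ratio vegetation index hyper", "GRVIHyper",
     "rho(560)/rho(658)", "LCC", ("EnMAP",), ""),
    ("Transformed chlorophyll absorption ratio", "TCARI",
     "3*((rho(700)-rho(670))-0.2*(rho(700)-rho(550))*(rho(700)/rho(670)))",
     "LCC", ("EnMAP",), ""),
    ("Triangular chlorophyll index", "TCI",
     "1.2*(rho(700)-rho(550))-1.5*(rho(670)-rho(550))*sqrt(rho(700)/rho(670))",
     "LCC", ("EnMAP",), ""),
    # --- LWC ---
    ("Modified normalized difference water index", "MNDWI",
     "(GREEN-rho(1600))/(GREEN+rho(1600))", "LWC", _ALL,
     "sources give a 1500-1700 nm band; the 1600 nm midpoint is used"),
    ("Moisture stress index", "MSI", "rho(1600)/rho(820)", "LWC", _ALL, ""),
    ("Shortwave infrared water stress index", "SIWSI",
     "(rho(800)-rho(1640))/(rho(800)+rho(1640))", "LWC", _ALL, ""),
    ("Normalized difference water index", "NDWI",
     "(rho(860)-rho(1240))/(rho(860)+rho(1240))", "LWC",
     ("MODIS", "Sentinel2", "Sentinel3", "EnMAP"), ""),
    ("Leaf water vegetation index 2", "LWVI2",
     "(rho(1094)-rho(1205))/(rho(1094)+rho(1205))", "LWC",
     ("Sentinel3", "EnMAP"), ""),
    ("Leaf water vegetation index 2 (SLSTR SWIR form)", "LWVI2_SWIR",
     "(rho(868)-rho(1613))/(rho(868)+rho(1613))", "LWC", ("Sentinel3",),
     "NIR/SWIR variant usable with the SLSTR band set"),
    ("Disease water stress index", "DSWI",
     "(rho(802)+rho(547))/(rho(1657)+rho(682))", "LWC", ("EnMAP",), ""),
    ("Disease water stress index 1", "DSWI1", "rho(800)/rho(1660)", "LWC",
     ("EnMAP",), ""),
    ("Leaf water vegetation index 1", "LWVI1",
     "(rho(1094)-rho(983))/(rho(1094)+rho(983))", "LWC", ("EnMAP",), ""),
    ("Normalized difference infrared index", "NDII",
     "(rho(819)-rho(1649))/(rho(819)+rho(1649))", "LWC", ("EnMAP",), ""),
    ("Water band index", "WBI", "rho(970)/rho(902)", "LWC", ("EnMAP",), ""),
    ("Water band index 4", "WBI4", "rho(895)/rho(972)", "LWC", ("EnMAP",), ""),
    ("Water content", "WC", "rho(1193)/rho(1126)", "LWC", ("EnMAP",), ""),
    ("Water index", "WI", "rho(900)/rho(970)", "LWC", ("EnMAP",), ""),
    ("Three-band ratio 1200", "Ratio1200",
     "2*rho(1205)/(rho(1095)+rho(1275))", "LWC", ("EnMAP",),
     "a misprinted 12755 nm band in some sources is read as 1275 nm"),
    # --- LAI ---
    ("Corrected transformed vegetation index", "CTVI",
     f"(({_NDVI}+0.5)/abs({_NDVI}+0.5))*sqrt(abs({_NDVI}+0.5))",
     "LAI", _ALL, ""),
    ("Difference vegetation index", "DVI", "NIR-RED", "LAI", _ALL,
     "difference form of the original publication"),
    ("Enhanced vegetation index", "EVI",
     "2.5*(NIR-RED)/((NIR+6*RED-7.5*BLUE)+1)", "LAI", _ALL, ""),
    ("Modified simple ratio", "MSR",
     "(rho(800)-rho(445))/(rho(680)-rho(445))", "LAI", _ALL, ""),
    ("Normalized difference vegetation index", "NDVI", _NDVI, "LAI", _ALL, ""),
    ("Specific leaf area vegetation index", "SLAVI",
     "NIR/(RED+SWIR)", "LAI", _ALL, ""),
    ("Wide dynamic range vegetation index", "WDRVI",
     "(0.1*NIR-RED)/(0.1*NIR+RED)", "LAI", _ALL, ""),
    ("Difference 1725/970 LAI index", "DLAI", "rho(1725)-rho(970)", "LAI",
     ("EnMAP",), ""),
    ("LAI determining index", "LAIDI", "rho(1250)/rho(1050)", "LAI",
     ("EnMAP",), ""),
]

_REGISTRY: dict[str, VIDefinition] = {}
for _name, _abbr, _expr, _target, _sensors, _notes in _DEFS:
    _REGISTRY[_abbr] = VIDefinition(
        name=_name, abbreviation=_abbr, expression=_expr,
        target_variable=_target, declared_sensors=tuple(_sensors), notes=_notes,
    )


def all_indices() -> list[VIDefinition]:
    """Every shipped index definition."""
    return list(_REGISTRY.values())


def get_index(abbreviation: str) -> VIDefinition:
    try:
        return _REGISTRY[abbreviation]
    except KeyError:
        raise KeyError(
            f"unknown index {abbreviation!r}; available: {sorted(_REGISTRY)}"
        ) from None


def builtin_registry(sensor: Sensor | str) -> list[VIDefinition]:
    """Shipped indices usable with the given sensor: declared for it *and*
    with every referenced band resolvable on its band set."""
    if isinstance(sensor, str):
        sensor = get_sensor(sensor)
    return [
        d for d in _REGISTRY.values()
        if sensor.name in d.declared_sensors and sensor_supports(d, sensor)
    ]
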