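"""Metabolism-module profiling: ordered gene lists with expression ratios.

A metabolism module is a gene list ordered by position in the metabolic
process (e.g. glycolysis steps).  Profiling attaches linear treatment/control
ratios by symbol (case-insensitive, with optional alias resolution for
transcription variants), keeps genes without a measured ratio as missing
rather than fabricating a neutral value, and summarizes regulation two ways:
the figures' criterion (ratio > 1 up, < 1 down, strict) and the screen's
criterion (ratio ≥ fc_up or ≤ fc_down), reported separately to avoid
conflation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .errors import InputError
from .diffexp import ScreenParams
from .io import ModuleFixture, norm_symbol

__all__ = ["MetabolismModule", "profile_module"]


@dataclass
class MetabolismModule:
    """An ordered module with attached ratios and regulation summary.

    ``ratios`` aligns with ``genes``; missing measurements are ``None``.
    Counts satisfy ``n_up + n_down + n_equal + n_missing == n_total``.
    """

    module_name: str
    genes: list[str]
    ratios: list[float | None]
    n_total: int = 0
    n_with_ratio: int = 0
    n_up: int = 0
    n_down: int = 0
    n_equal: int = 0
    n_missing: int = 0
    n_pass_screen: int = 0
    summary: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "module_name": self.module_name,
            "genes": self.genes,
            "ratios": self.ratios,
            "n_total": self.n_total,
            "n_with_ratio": self.n_with_ratio,
            "n_up": self.n_up,
            "n_down": self.n_down,
            "n_equal": self.n_equal,
            "n_missing": self.n_missing,
            "n_pass_screen": self.n_pass_screen,
        }


def profile_module(ordered_genes: Sequence[str] | ModuleFixture,
                   ratios: pd.Series | Mapping[str, float],
                   params: ScreenParams | None = None,
                   aliases: Mapping[str, str] | None = None,
                   module_name: str = "module") -> MetabolismModule:
    """Attach ratios to an ordered gene list and summarize regulation.

    Parameters
    ----------
    ordered_genes
        The module's gene symbols in metabolic-process order (or a packaged
        :class:`~starchnet.io.ModuleFixture`, whose aliases are applied).
    ratios
        Per-symbol linear ratios (e.g. the ``ratio`` column of a DEG table);
        matched case-insensitively.
    params
        Screen thresholds for ``n_pass_screen`` (defaults used if omitted).
    aliases
        Extra normalized-spelling → normalized-canonical-symbol mapping.
    """
    if isinstance(ordered_genes, ModuleFixture):
        fixture = ordered_genes
        genes = list(fixture.symbols)
        alias_map = dict(fixture.aliases)
        module_name = fixture.module_name
    else:
        genes = list(ordered_genes)
        alias_map = {}
    if aliases:
        alias_map.update({norm_symbol(k): norm_symbol(v) for k, v in aliases.items()})
    if not genes:
        raise InputError("module gene list is empty")
    keys = [alias_map.get(norm_symbol(g), norm_symbol(g)) for g in genes]
    dup = {k for k in keys if keys.count(k) > 1}
    if dup:
        raise InputError(f"duplicate symbol(s) in module list: {sorted(dup)}")

    if params is None:
        params = ScreenParams()
    if isinstance(ratios, pd.Series):
        ratio_map = {norm_symbol(str(g)): float(v) for g, v in ratios.items()}
    else:
        ratio_map = {norm_symbol(str(g)): float(v) for g, v in ratios.items()}

    attached: list[float | None] = [ratio_map.get(k) for k in keys]
    measured = [r for r in attached if r is not None and math.isfinite(r)]
    n_up = sum(1 for r in measured if r > 1)
    n_down = sum(1 for r in measured if r < 1)
    n_equal = sum(1 for r in measured if r == 1)
    n_pass = sum(1 for r in measured if r >= params.fc_up or r <= params.fc_down)

    return MetabolismModule(
        module_name=module_name,
        genes=genes,
        ratios=attached,
        n_total=len(genes),
        n_with_ratio=len(measured),
        n_up=n_up,
        n_down=n_down,
        n_equal=n_equal,
        n_missing=len(genes) - len(measured),
        n_pass_screen=n_pass,
    )
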