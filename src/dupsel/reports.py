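"""Report assembly: TSV tables with fixed rounding plus full-precision JSON.

Rounding conventions follow molecular-evolution table practice: NI to 2
decimals, chi-square to 1, p-values to 3.  Range cells are rendered
"min-max" (en dash) when the ends differ, and conservative bounds as
"<=x" / ">=y".  The TSV is a deterministic formatting of the JSON values,
so the two artifacts always agree.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Any, Sequence

from dupsel.codonmodel import LRTResult
from dupsel.mk import MKRangeResult, MKResult

EN_DASH = "–"
LEQ = "≤"
GEQ = "≥"

MK_COLUMNS = ["syn_poly", "nsyn_poly", "syn_sub", "nsyn_sub", "NI", "chi2", "P"]
SCAN_COLUMNS = ["branch", "stat", "df", "p_raw", "p_adjusted", "lnL_alt",
                "lnL_null", "converged"]


def _fmt(x: float, nd: int) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return f"{x:.{nd}f}"


def _fmt_range(lo: float, hi: float, nd: int) -> str:
    if abs(hi - lo) < 0.5 * 10 ** (-nd):
        return _fmt(lo, nd)
    return f"{_fmt(lo, nd)}{EN_DASH}{_fmt(hi, nd)}"


def mk_result_row(res: MKResult) -> dict[str, Any]:
    c = res.counts
    return {
        "label": res.label,
        "syn_poly": None if c is None else c.Ps,
        "nsyn_poly": None if c is None else c.Pn,
        "syn_sub": None if c is None else c.Ds,
        "nsyn_sub": None if c is None else c.Dn,
        "NI": None if not res.ni_defined else res.NI,
        "chi2": None if not res.chi2_defined else res.chi2,
        "P": None if not res.chi2_defined else res.p,
    }


def mk_range_row(res: MKRangeResult) -> dict[str, Any]:
    return {
        "label": res.label,
        "syn_poly": res.Ps,
        "nsyn_poly": res.Pn,
        "syn_sub": list(res.Ds_range),
        "nsyn_sub": list(res.Dn_range),
        "NI_max": res.NI_max if not math.isnan(res.NI_max) else None,
        "chi2_min": res.chi2_min if not math.isnan(res.chi2_min) else None,
        "P": res.p_at_chi2_min if not math.isnan(res.p_at_chi2_min) else None,
    }


def _mk_tsv_line(res: MKResult | MKRangeResult) -> str:
    if isinstance(res, MKRangeResult):
        cells = [res.label,
                 _fmt(res.Ps, 1), _fmt(res.Pn, 1),
                 _fmt_range(*res.Ds_range, 1), _fmt_range(*res.Dn_range, 1),
                 f"{LEQ}{_fmt(res.NI_max, 2)}" if not math.isnan(res.NI_max) else "NA",
                 f"{GEQ}{_fmt(res.chi2_min, 1)}" if not math.isnan(res.chi2_min) else "NA",
                 _fmt(res.p_at_chi2_min, 3)]
    else:
        c = res.counts
        cells = [res.label,
                 _fmt(c.Ps if c else math.nan, 1), _fmt(c.Pn if c else math.nan, 1),
                 _fmt(c.Ds if c else math.nan, 1), _fmt(c.Dn if c else math.nan, 1),
                 _fmt(res.NI, 2) if res.ni_defined else "NA",
                 _fmt(res.chi2, 1) if res.chi2_defined else "NA",
                 _fmt(res.p, 3) if res.chi2_defined else "NA"]
    return "\t".join(cells)


def scan_row(res: LRTResult) -> dict[str, Any]:
    return {
        "branch": res.foreground_branch,
        "stat": res.stat,
        "df": res.df,
        "p_raw": res.p_raw,
        "p_adjusted": res.p_adjusted,
        "lnL_alt": None if math.isnan(res.lnL_alt) else res.lnL_alt,
        "lnL_null": None if math.isnan(res.lnL_null) else res.lnL_null,
        "converged": res.converged,
    }


def _scan_tsv_line(res: LRTResult) -> str:
    return "\t".join([
        str(res.foreground_branch), _fmt(res.stat, 2), str(res.df),
        _fmt(res.p_raw, 4),
        _fmt(res.p_adjusted, 4) if res.p_adjusted is not None else "NA",
        _fmt(res.lnL_alt, 4), _fmt(res.lnL_null, 4), str(res.converged),
    ])


def provenance(config: dict[str, Any], seed: int | None = None) -> dict[str, Any]:
    """Reproducibility block: canonical config hash plus the seed used."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    out = {"config_hash": hashlib.sha256(blob).hexdigest()[:16], "config": config}
    if seed is not None:
        out["seed"] = seed
    return out


def write_report(results: Sequence[MKResult | MKRangeResult | LRTResult],
                 layout: str, out_prefix: str | Path,
                 meta: dict[str, Any] | None = None) -> tuple[Path, Path]:
    """Write a TSV + JSON report pair for one result set.

    ``layout`` is ``table2`` (MK vs references, range cells allowed),
    ``table3`` (pairwise MK) or ``scan`` (branch-site LRTs).  Returns the
    two paths written.  An empty result set is an error and writes nothing.
    """
    if not results:
        raise ValueError("refusing to write an empty report")
    if layout not in ("table2", "table3", "scan"):
        raise ValueError(f"unknown layout {layout!r}")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv_path = out_prefix.with_suffix(".tsv")
    json_path = out_prefix.with_suffix(".json")

    if layout == "scan":
        header = "\t".join(SCAN_COLUMNS)
        lines = [header] + [_scan_tsv_line(r) for r in results]
        rows = [scan_row(r) for r in results]
    else:
        header = "\t".join(["comparison"] + MK_COLUMNS)
        lines = [header] + [_mk_tsv_line(r) for r in results]
        rows = [mk_range_row(r) if isinstance(r, MKRangeResult) else mk_result_row(r)
                for r in results]
    tsv_path.write_text("\n".join(lines) + "\n")
    payload: dict[str, Any] = {"layout": layout, "rows": rows}
    if meta:
        payload["provenance"] = meta
    json_path.write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")
    return tsv_path, json_path


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
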