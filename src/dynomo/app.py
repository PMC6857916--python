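"""The dynamic nomogram: input controls derived from a fitted model,
accumulated prediction scenarios, summary views, and a deployable bundle.

This layer performs no statistics of its own — every displayed number
comes from :mod:`dynomo.prediction` — it only shapes model metadata into
controls (sliders bounded by observed covariate ranges, drop-downs for
factor levels, defaults at the mean/mode) and accumulates scenarios into
view-model JSON that any UI can render.  A minimal local web UI ships as
reference (:func:`serve_model`).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fitting import CoxModel, FittedModel, export_model, import_model
from .prediction import (
    PredictionResult,
    SurvivalCurve,
    predict_response,
    survival_curve,
)
from scipy import stats

__all__ = [
    "ControlSpec",
    "SessionState",
    "control_spec",
    "add_scenario",
    "numerical_summary",
    "model_summary",
    "scenario_view_model",
    "export_bundle",
    "serve_model",
]

#: alpha-blending floor: survival lines never drop below this opacity
MIN_ALPHA = 0.1


def _nice_step(span: float) -> float:
    """range/100 rounded to a presentable 1–2 significant-figure increment."""
    if span <= 0:
        return 1.0
    raw = span / 100.0
    mag = 10.0 ** math.floor(math.log10(raw))
    for mult in (1.0, 2.0, 2.5, 5.0, 10.0):
        if raw <= mult * mag * 1.0000001:
            return mult * mag
    return 10.0 * mag


@dataclass
class ControlSpec:
    variable: str
    widget: str  # slider | dropdown
    min: float | None = None
    max: float | None = None
    step: float | None = None
    options: tuple[str, ...] = ()
    default: object = None


@dataclass
class SessionState:
    """Accumulated prediction scenarios for one model."""

    model: object
    level: float = 0.95
    scenarios: list[tuple[dict, object]] = field(default_factory=list)


def control_spec(model) -> list[ControlSpec]:
    """One control per model variable, in formula order.

    Covariates become sliders bounded by the observed range with the mean
    as default; factors become drop-downs defaulting to the mode.
    """
    controls = []
    for name in model.formula.variable_names:
        spec = model.variable_specs[name]
        if spec.role == "factor":
            controls.append(
                ControlSpec(variable=name, widget="dropdown",
                            options=spec.levels, default=spec.mode)
            )
        else:
            controls.append(
                ControlSpec(
                    variable=name, widget="slider",
                    min=spec.observed_min, max=spec.observed_max,
                    step=_nice_step(spec.observed_max - spec.observed_min),
                    default=spec.mean,
                )
            )
    return controls


def add_scenario(state: SessionState, inputs: dict) -> SessionState:
    """Append a prediction (or survival curve for Cox) for ``inputs``.

    Invalid inputs raise and leave the state unchanged; duplicates are
    appended, not merged, so scenario indices stay stable.
    """
    if isinstance(state.model, CoxModel):
        result = survival_curve(state.model, inputs)
    else:
        result = predict_response(state.model, inputs, level=state.level)
    state.scenarios.append((dict(inputs), result))
    return state


def numerical_summary(state: SessionState, precision: int = 2):
    """One row per scenario: inputs + estimate and interval limits.

    For Cox sessions the tabulated quantity is the survival probability at
    the median observed event time.  Returns a pandas DataFrame; empty
    state gives an empty frame.
    """
    import pandas as pd

    rows = []
    for i, (inputs, result) in enumerate(state.scenarios, start=1):
        row = {"scenario": i, **inputs}
        if isinstance(result, SurvivalCurve):
            t_med = float(np.median(result.times)) if result.times.size else 0.0
            row["time"] = t_med
            row["estimate"] = round(result.at(t_med), precision)
        else:
            row["estimate"] = round(result.response_estimate, precision)
            row["lower"] = round(result.response_lower, precision)
            row["upper"] = round(result.response_upper, precision)
        rows.append(row)
    return pd.DataFrame(rows)


def _p_value(model, stat: float) -> float:
    if getattr(model, "family", None) in ("gaussian", "gamma"):
        return float(2 * stats.t.sf(abs(stat), model.df_residual))
    return float(2 * stats.norm.sf(abs(stat)))


def model_summary(model) -> str:
    """Formatted coefficient table, one line per design column.

    GLMs print Estimate / Std. Error / statistic / p-value; Cox models add
    hazard ratios with confidence limits.
    """
    se = np.sqrt(np.diag(model.sigma))
    lines = []
    if isinstance(model, CoxModel):
        head = f"Cox proportional hazards model  (ties: {model.ties})"
        lines.append(head)
        lines.append(f"n = {model.n_used}, events = {model.n_events}, "
                     f"log partial-likelihood = {model.loglik:.2f}")
        lines.append("")
        lines.append(f"{'':>16}  {'Estimate':>9} {'Std. Error':>10} {'HRatio':>7} "
                     f"{'95% CI':>14} {'p-value':>8}")
        z975 = stats.norm.ppf(0.975)
        for name, b, s in zip(model.column_labels, model.beta, se):
            z = b / s if s > 0 else 0.0
            hr = math.exp(b)
            ci = f"({math.exp(b - z975 * s):.2f}, {math.exp(b + z975 * s):.2f})"
            lines.append(
                f"{name:>16}  {b:>9.4f} {s:>10.4f} {hr:>7.2f} {ci:>14} "
                f"{_fmt_p(_p_value(model, z)):>8}"
            )
    else:
        stat_name = "t-value" if model.family in ("gaussian", "gamma") else "z-value"
        lines.append(f"{model.family} model, {model.link} link")
        lines.append(f"n = {model.n_used}, df.residual = {model.df_residual}, "
                     f"dispersion = {model.dispersion:.4g}, "
                     f"log-likelihood = {model.loglik:.2f}")
        lines.append("")
        lines.append(f"{'':>16}  {'Estimate':>9} {'Std. Error':>10} "
                     f"{stat_name:>8} {'p-value':>8}")
        for name, b, s in zip(model.column_labels, model.beta, se):
            z = b / s if s > 0 else 0.0
            lines.append(
                f"{name:>16}  {b:>9.4f} {s:>10.4f} {z:>8.2f} "
                f"{_fmt_p(_p_value(model, z)):>8}"
            )
    return "\n".join(lines)


def _fmt_p(p: float) -> str:
    return "<0.0001" if p < 1e-4 else f"{p:.4f}"


def scenario_view_model(state: SessionState) -> dict:
    """JSON-ready plot data: points + intervals, or alpha-blended step
    curves for Cox sessions (opacity = at-risk fraction, floored)."""
    out = {"level": state.level, "kind": None, "scenarios": []}
    for i, (inputs, result) in enumerate(state.scenarios, start=1):
        if isinstance(result, SurvivalCurve):
            out["kind"] = "survival"
            out["scenarios"].append(
                {
                    "index": i,
                    "inputs": inputs,
                    "times": result.times.tolist(),
                    "survival": result.survival.tolist(),
                    "alpha": np.maximum(result.at_risk_fraction, MIN_ALPHA).tolist(),
                }
            )
        else:
            out["kind"] = "prediction"
            out["scenarios"].append(
                {
                    "index": i,
                    "inputs": inputs,
                    "estimate": result.response_estimate,
                    "lower": result.response_lower,
                    "upper": result.response_upper,
                }
            )
    return out


# --------------------------------------------------------------------------
# deployable bundle

_APP_TEMPLATE = """\
#!/usr/bin/env python
\"\"\"Self-contained dynamic-nomogram app for a serialized model.

Run `python app.py [port]` and open the printed URL.  Requires only the
dynomo package; the training data is not needed.
\"\"\"
import sys
from pathlib import Path

from dynomo.app import serve_model

if __name__ == "__main__":
    port = int(sys.argv[1]) if len(sys.argv) > 1 else 8050
    serve_model(Path(__file__).parent / "model.json", port=port)
"""


def export_bundle(model, outdir) -> Path:
    """Write a deployable app directory for ``model``.

    Contents: ``model.json`` (serialized model), ``config.json`` (control
    specs + default confidence level), ``app.py`` (entry script) and
    ``manifest.json`` listing every emitted file with its sha256.  The
    bundle is hermetic: predictions served from it depend only on
    ``model.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    export_model(model, outdir / "model.json")
    controls = [
        {k: (list(v) if isinstance(v, tuple) else v)
         for k, v in vars(c).items()}
        for c in control_spec(model)
    ]
    (outdir / "config.json").write_text(
        json.dumps({"controls": controls, "level": 0.95}, indent=1, sort_keys=True)
    )
    (outdir / "app.py").write_text(_APP_TEMPLATE)
    files = ["model.json", "config.json", "app.py"]
    manifest = {
        "format": "dynomo-bundle",
        "version": 1,
        "files": {
            f: hashlib.sha256((outdir / f).read_bytes()).hexdigest() for f in files
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return outdir


# --------------------------------------------------------------------------
# minimal reference web UI (stdlib only)

_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>dynomo</title>
<style>body{font-family:sans-serif;margin:2em;max-width:720px}
label{display:block;margin:.6em 0}#out{white-space:pre;margin-top:1em;
background:#f4f4f4;padding:1em;border-radius:6px}</style></head>
<body><h2>Dynamic nomogram</h2><form id="f"></form>
<button onclick="go()">Predict</button><div id="out"></div>
<script>
let controls = [];
fetch('controls').then(r=>r.json()).then(cs=>{controls=cs;
 const f=document.getElementById('f');
 cs.forEach(c=>{const l=document.createElement('label');
  if(c.widget==='slider'){l.innerHTML=`${c.variable}: <input type="range" id="${c.variable}"
   min="${c.min}" max="${c.max}" step="${c.step}" value="${c.default}"
   oninput="this.nextElementSibling.textContent=this.value"><span>${c.default}</span>`;}
  else{l.innerHTML=`${c.variable}: <select id="${c.variable}">`+
   c.options.map(o=>`<option ${o===c.default?'selected':''}>${o}</option>`).join('')+'</select>';}
  f.appendChild(l);});});
function go(){const inputs={};controls.forEach(c=>{
  const v=document.getElementById(c.variable).value;
  inputs[c.variable]=c.widget==='slider'?parseFloat(v):v;});
 fetch('predict',{method:'POST',headers:{'Content-Type':'application/json'},
  body:JSON.stringify({inputs:inputs})}).then(r=>r.json())
  .then(d=>{document.getElementById('out').textContent=JSON.stringify(d,null,2);});}
</script></body></html>
"""


def serve_model(model_path, port: int = 8050, open_browser: bool = False):
    """Serve the reference UI for a serialized model (blocking)."""
    import http.server

    model = import_model(Path(model_path))
    controls = control_spec(model)

    class Handler(http.server.BaseHTTPRequestHandler):
        def _send(self, body: bytes, ctype: str):
            self.send_response(200)
            self.send_header("Content-Type", ctype)
            self.send_header("Content-Length", str(len(body)))
            self.end_headers()
            self.wfile.write(body)

        def do_GET(self):
            if self.path.rstrip("/") in ("", "/index.html"):
                self._send(_PAGE.encode(), "text/html; charset=utf-8")
            elif self.path.endswith("controls"):
                payload = [
                    {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in vars(c).items()}
                    for c in controls
                ]
                self._send(json.dumps(payload).encode(), "application/json")
            else:
                self.send_error(404)

        def do_POST(self):
            length = int(self.headers.get("Content-Length", 0))
            req = json.loads(self.rfile.read(length) or b"{}")
            state = SessionState(model=model, level=req.get("level", 0.95))
            add_scenario(state, req.get("inputs", {}))
            self._send(
                json.dumps(scenario_view_model(state)).encode(), "application/json"
            )

        def log_message(self, *args):  # quiet server
            pass

    server = http.server.HTTPServer(("127.0.0.1", port), Handler)
    print(f"dynomo: serving on http://127.0.0.1:{port}/ (Ctrl-C to stop)")
    try:
        server.serve_forever()
    except KeyboardInterrupt:
        pass
    finally:
        server.server_close()
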