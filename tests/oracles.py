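"""Independent oracles used by the acceptance tests.

The mixed-model fits are verified against lme4 (via Rscript), the
reference implementation for this model class.  For each model the oracle
takes the best of three lme4 optimizers, so occasional singular-fit
stalls of a single optimizer do not masquerade as disagreement.
"""

from __future__ import annotations

import json
import shutil
import subprocess

import pandas as pd

_FORMULAS = {
    "empty2": "y ~ 1 + (1 | PersonF)",
    "empty3": "y ~ 1 + (1 | PersonF) + (1 | DayF)",
    "ar2": "y ~ 1 + lev1pred + (1 | PersonF) + (0 + lev1pred | PersonF)",
    "ar2corr": "y ~ 1 + lev1pred + (1 + lev1pred | PersonF)",
    "ar3_nobeta": (
        "y ~ 1 + lev1predfor3l + (1 | PersonF) + (1 | DayF) "
        "+ (0 + lev1predfor3l | PersonF)"
    ),
    "ar3_fixedbeta": (
        "y ~ 1 + lev2pred + lev1predfor3l + (1 | PersonF) + (1 | DayF) "
        "+ (0 + lev1predfor3l | PersonF)"
    ),
    "ar3_randombeta": (
        "y ~ 1 + lev2pred + lev1predfor3l + (1 | PersonF) + (1 | DayF) "
        "+ (0 + lev2pred | PersonF) + (0 + lev1predfor3l | PersonF)"
    ),
    "ar3_fixedonly": (
        "y ~ 1 + lev2pred + lev1predfor3l + (1 | PersonF) + (1 | DayF)"
    ),
}

_R_TEMPLATE = """
suppressMessages(library(lme4))
d <- read.csv("{csv}")
spec <- read.csv("{spec_csv}", stringsAsFactors = FALSE)
forms <- list({formulas})
out <- file("{out}", "w")
for (k in seq_len(nrow(spec))) {{
  i <- spec$instance[k]; fam <- spec$family[k]
  di <- d[d$instance == i, ]
  di$PersonF <- factor(di$person)
  di$DayF <- factor(paste(di$person, di$day))
  best_ll <- -Inf; best_fe <- NULL
  for (opt in c("default", "bobyqa", "Nelder_Mead")) {{
    ctrl <- if (opt == "default") lmerControl() else lmerControl(optimizer = opt)
    m <- try(suppressMessages(suppressWarnings(
      lmer(forms[[fam]], data = di, REML = FALSE, control = ctrl))), silent = TRUE)
    if (inherits(m, "try-error")) next
    ll <- as.numeric(logLik(m))
    if (ll > best_ll) {{ best_ll <- ll; best_fe <- fixef(m) }}
  }}
  cat(sprintf('{{"instance": %d, "family": "%s", "ll": %.10f, "fe": [%s]}}\\n',
      i, fam, best_ll, paste(sprintf("%.10f", best_fe), collapse = ",")), file = out)
}}
close(out)
"""


def lme4_available() -> bool:
    return shutil.which("Rscript") is not None


def lme4_fits(
    instances: dict[int, pd.DataFrame],
    jobs: list[tuple[int, str]],
    workdir,
) -> dict[tuple[int, str], dict]:
    """Fit (instance, family) jobs with lme4; returns loglik + fixed effects.

    ``instances`` maps instance ids to listwise-complete data frames with
    person/day/y and predictor columns; all fits run in one R session.
    """
    if not lme4_available():
        raise RuntimeError("Rscript not found; lme4 oracle unavailable")
    csv = workdir / "oracle_data.csv"
    frames = []
    for i, df in instances.items():
        f = df.copy()
        f["instance"] = i
        frames.append(f)
    pd.concat(frames).to_csv(csv, index=False)
    spec_csv = workdir / "oracle_jobs.csv"
    pd.DataFrame(jobs, columns=["instance", "family"]).to_csv(spec_csv, index=False)
    out = workdir / "oracle_out.jsonl"
    formulas = ", ".join(f'{fam} = {f}' for fam, f in _FORMULAS.items())
    script = workdir / "oracle.R"
    script.write_text(
        _R_TEMPLATE.format(csv=csv, spec_csv=spec_csv, out=out, formulas=formulas)
    )
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True, timeout=1200)
    results = {}
    for line in out.read_text().splitlines():
        rec = json.loads(line)
        results[(rec["instance"], rec["family"])] = rec
    return results
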