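"""Registering a third-party back-calculator as a CLI subcommand.

External predictors (chemical shifts, SAXS profiles, hydrodynamic radii, ...)
can plug into the same ensemble/template/JSON pipeline: register a callable
taking (ensemble, template_path, config) and returning a BackcalcResult, and
it becomes a subcommand with the standard options.
"""

from click.testing import CliRunner

from idpcalc import register_backcalculator
from idpcalc.cli import main
from idpcalc.templates import BackcalcResult, parse_template

import tempfile
from pathlib import Path

from idpcalc.synthetic import generate_ensemble, generate_template


def radius_of_gyration(ensemble, template_path, config):
    """Toy example: one Rg value (A) per conformer, ignoring the template rows."""
    import numpy as np
    template = parse_template(template_path, "pre")
    per_conformer = {}
    for conf in ensemble:
        xyz = np.array([a.coord for a in conf.atoms])
        rg = float(np.sqrt(((xyz - xyz.mean(axis=0)) ** 2).sum(axis=1).mean()))
        per_conformer[conf.label] = [rg] * len(template)
    return BackcalcResult("rg", template.format_echo(), per_conformer)


register_backcalculator("rg", radius_of_gyration)

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    ens = generate_ensemble(tmp / "pdbs", 5, seed=3)
    generate_template(ens, "pre", 1, seed=1, path=tmp / "t.csv")
    result = CliRunner().invoke(main, [
        "rg", "--pdbs", str(tmp / "pdbs"), "--exp-file", str(tmp / "t.csv"),
        "--output", str(tmp / "rg.json")])
    print("exit code:", result.exit_code)
    print((tmp / "rg.json").read_text())

print("The registered subcommand honours the JSON contract: a 'format' echo "
      "plus one value list per conformer, in ensemble order.")
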