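"""Use the registry the way the command line does, but from Python.

Instantiates a bundled challenge, fetches its synthetic template and gold
standard, and scores the template — the same three-call contract every
challenge (bundled or scaffolded plugin) follows.  The equivalent shell
session:

    dreambench --challenge D3C3 --download-template
    dreambench --challenge D3C3 --filename <template> --json
"""

from dreambench import default_registry

registry = default_registry()
print(registry.info("D3C3"))
print()

challenge = registry.challenge("D3C3")
template = challenge.download_template()
gold = challenge.download_goldstandard()
print(f"template: {template}")
print(f"gold:     {gold}")

report = challenge.score(template)
print(f"p_time = {report['p_time']:.4g}, p_gene = {report['p_gene']:.4g}")
print(f"final score -1/2 log10(p_T * p_G) = {report['final']:.3f}")
print("The template is a deliberately mediocre example submission, so the")
print("score sits well below what scoring the gold standard itself yields.")
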