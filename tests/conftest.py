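import tempfile

from hypothesis import configuration, settings

# keep hypothesis' scratch storage (constants cache etc.) out of the repo
configuration.set_hypothesis_home_dir(tempfile.mkdtemp(prefix="hypothesis-"))

# stateless and deterministic: no on-disk example database, fixed derivation
settings.register_profile("dlg", database=None, derandomize=True, deadline=None)
settings.load_profile("dlg")
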