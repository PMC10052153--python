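Traceback (most recent call last):
  File "<string>", line 2, in <module>
ModuleNotFoundError: No module named 'proto'
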