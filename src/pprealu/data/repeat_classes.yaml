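# Controlled vocabulary for repeat class/family labels.
# Keys are raw labels as they appear in annotation files; values are the
# canonical labels used throughout the pipeline.  Unknown labels pass
# through with a warning.  Simple_repeat is deliberately kept distinct
# from Low_complexity.
classes:
  SINE/Alu: SINE/Alu
  SINE/ALU: SINE/Alu
  Alu: SINE/Alu
  LINE/L1: LINE/L1
  L1: LINE/L1
  Low_complexity: Low_complexity
  Low complexity: Low_complexity
  Simple_repeat: Simple_repeat
  Simple repeat: Simple_repeat
  SINE/MIR: SINE/MIR
  LINE/L2: LINE/L2
  LTR/ERVL: LTR/ERVL
  LTR/ERV1: LTR/ERV1
  DNA/hAT-Charlie: DNA/hAT-Charlie
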