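year,total_valid,in_homes
1998,9093,457
2000,11199,784
2002,16064,740
2005,15638,422
2008,16954,308
2011,9638,207
2014,7020,198
2018,15549,574
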