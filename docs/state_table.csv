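code,label,activity,lumen_category,pressure_category
oq,occluded quiescence,passive,occluded,static
oimc,occluded isometric contraction,active,occluded,increasing
oimr,occluded isometric relaxation,active,occluded,decreasing
dq,distended quiescence,passive,static,static
dipi,distended isometric pressure increase,active,static,increasing
dipd,distended isometric pressure decrease,active,static,decreasing
itr,isotonic relaxation,active,increasing,static
pd,passive dilatation,passive,increasing,increasing
atr,auxotonic relaxation,active,increasing,decreasing
itc,isotonic contraction,active,decreasing,static
atc,auxotonic contraction,active,decreasing,increasing
ps,passive shortening,passive,decreasing,decreasing
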