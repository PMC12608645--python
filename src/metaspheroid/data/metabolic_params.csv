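reaction_id,parameter,value,units,source
r1,vmax,0.7,mM/min,calibrated basal glucose uptake
r1,km,1.5,mM,GLUT1-range affinity
r2,k,1.2,mM/min,model default
r2,km_glc,0.3,mM,model default
r2,km_atp,0.15,mM,model default
r2,ki_g6p,0.5,mM,product inhibition
r3,k,20.0,1/min,fast equilibration
r3,keq,0.3,-,F6P/G6P equilibrium ratio
r4,k,0.9,mM/min,calibrated glycolytic capacity
r4,km_f6p,0.05,mM,model default
r4,km_atp,0.15,mM,model default
r4,ka_amp,0.1,mM,AMP allosteric activation
r4,ki_atp,2.0,mM,ATP allosteric inhibition
r4,hif_relax,0.5,-,HIF relieves the ATP clamp (aerobic glycolysis)
r4,ki_lac,3.0,mM,lactate product inhibition of glycolysis
r4,amp_boost,4.0,-,AMP allosteric activation
r5,k,8.0,1/min,fast step
r6,k,20.0,1/min,fast equilibration
r6,keq,0.1,-,GAP/DHAP equilibrium ratio
r7,k,40.0,1/min,fast step
r7,km_nad,0.1,mM,NAD+ dependence
r8,k,40.0,1/min,fast step
r8,km_adp,0.3,mM,model default
r9,k,30.0,1/min,fast equilibration
r9,keq,0.2,-,PG2/PG3 equilibrium ratio
r10,k,30.0,1/min,fast equilibration
r10,keq,1.5,-,PEP/PG2 equilibrium ratio
r11,k,2.0,mM/min,model default
r11,km_pep,0.03,mM,model default
r11,km_adp,0.3,mM,model default
r11,ka_fbp,0.2,mM,FBP feedforward activation
r11,fbp_boost,1.0,-,FBP feedforward activation
r12,kf,400.0,1/(mM.min),calibrated fermentative capacity
r12,keq,1000.0,-,equilibrium strongly favors lactate
r12,km_pyr,2.0,mM,saturation
r12,km_lac,10.0,mM,saturation
r13,k,0.05,mM/min,slow storage
r13,km_glc,0.3,mM,model default
r13,gly_max,6.0,mM,"store capacity, glucose equivalents"
r14,k,0.02,mM/min,store mobilization
r14,km_gly,1.0,mM,model default
r14,ki_glc,0.15,mM,released only when intracellular glucose is low
r15,k,40.0,1/min,malate-aspartate shuttle lump
r15,keq,10.0,-,shuttle favors import
r16,k,5.0,mM/min,calibrated basal ATP turnover
r16,km_atp,0.5,mM,demand saturates in ATP
r16,ampk_relief,0.4,-,AMPK damps consumption
r16,km_ampk,1.0,-,AMPK damps consumption
r17,k,12.0,1/(mM.min),fast equilibration
r17,keq,1.0,-,ADP^2 = ATP*AMP
r18,k,2.0,mM/min,calibrated respiratory capacity
r18,km_pyr,0.02,mM,model default
r18,km_nadm,0.1,mM,NAD+ dependence
r18,km_coa,0.05,mM,CoA dependence
r19,k,20.0,mM/min,fast step
r19,km_accoa,0.05,mM,model default
r19,km_oaa,0.01,mM,model default
r20,k,20.0,1/min,fast equilibration
r20,keq,0.2,-,ICIT/CIT equilibrium ratio
r21,vmax,1.0,mM/min,calibrated transport capacity
r21,km,2.0,mM,saturation of the product driving force
r22,k,3.0,mM/min,model default
r22,km_icit,0.06,mM,model default
r22,km_nadm,0.1,mM,NAD+ dependence
r23,k,3.0,mM/min,model default
r23,km_akg,0.2,mM,model default
r23,km_nadm,0.1,mM,NAD+ dependence
r23,km_coa,0.05,mM,CoA dependence
r24,k,10.0,1/min,fast step
r24,km_adp,0.3,mM,model default
r25,k,2.0,mM/min,model default
r25,km_suc,0.5,mM,model default
r25,km_fad,0.02,mM,FAD dependence
r26,k,20.0,1/min,fast equilibration
r26,keq,3.0,-,MAL/FUM equilibrium ratio
r27,kf,20.0,1/min,model default
r27,keq,0.1,-,equilibrium disfavors OAA
r28,k,12.0,mM/min,calibrated oxidative capacity
r28,km_nadhm,0.1,mM,model default
r28,km_o2,0.009,mM,"half-max oxygen (~7 mmHg), cubic"
r28,km_adp,0.08,mM,respiratory control
r28,atp_per_nadh,2.5,-,P/O stoichiometry
r29,k,12.0,mM/min,calibrated oxidative capacity
r29,km_fadh2,0.02,mM,model default
r29,km_o2,0.009,mM,"half-max oxygen (~7 mmHg), cubic"
r29,km_adp,0.08,mM,respiratory control
r29,atp_per_fadh2,1.5,-,P/O stoichiometry
r30,k,4.0,1/min,pH-i regulation
r30,ph_set,7.1,pH,intracellular set point
ph,mid_e,6.6,pH,extracellular sigmoid midpoint
ph,width_e,0.2,pH,extracellular sigmoid steepness
ph,anchor_e,7.4,pH,no inhibition at physiological pH
ph,mid_i,6.9,pH,intracellular sigmoid midpoint
ph,width_i,0.15,pH,intracellular sigmoid steepness
ph,anchor_i,7.1,pH,no inhibition at the pH-i set point
proton,href,3.9810717055349695e-05,mM,free H+ at pH 7.4
proton,buffer_i,2000.0,-,intracellular buffering capacity
proton,buffer_e,30.0,-,effective extracellular buffering
hif1a,a,0.0333,1/min,constitutive production
hif1a,kdeg,0.1665,1/min,maximal degradation
hif1a,basal_frac,0.1,-,oxygen-independent degradation
hif1a,km_o2,0.01,mM,"PHD oxygen sensing, quadratic"
hif1a,km_lac,1.0,mM,lactate stabilization
hif1a,lac_floor,0.25,-,residual degradation at saturating lactate
ampk,a0,0.005,1/min,basal production
ampk,a,0.05,1/min,activation under ATP depletion
ampk,km_atp,1.0,mM,ATP sensing
ampk,kdeg,0.05,1/min,turnover
p53,a0,0.002,1/min,basal production
p53,a,0.008,1/min,AMPK-driven activation
p53,km_ampk,1.0,-,model default
p53,kdeg,0.00833,1/min,turnover
myc,a,0.01,1/min,"production, p53-repressed"
myc,ki_p53,1.5,-,p53 repression
myc,kdeg,0.00833,1/min,turnover
pdk,a0,0.00167,1/min,basal production
pdk,a,0.015,1/min,HIF-driven production
pdk,km_hif,0.8,-,HIF response
pdk,kdeg,0.00833,1/min,turnover
glut,a0,0.0055,1/min,basal production
glut,a_hif,0.02,1/min,HIF-driven production
glut,a_myc,0.004,1/min,MYC-driven production
glut,km_hif,0.8,-,HIF response
glut,km_myc,1.0,-,MYC response
glut,ki_p53,2.0,-,p53 repression
glut,kdeg,0.00833,1/min,turnover
ldh,a0,0.00417,1/min,basal production
ldh,a_hif,0.042,1/min,HIF-driven production
ldh,a_myc,0.004,1/min,MYC-driven production
ldh,km_hif,0.8,-,HIF response
ldh,km_myc,1.0,-,MYC response
ldh,kdeg,0.00833,1/min,turnover
pdh,a,0.0098,1/min,production
pdh,ki_pdk,1.2,-,PDK repression
pdh,a_p53,0.5,-,p53 support
pdh,km_p53,1.5,-,p53 response
pdh,kdeg,0.00833,1/min,turnover
mct,a0,0.007,1/min,basal production
mct,a_hif,0.0083,1/min,HIF-driven production
mct,km_hif,0.8,-,HIF response
mct,kdeg,0.00833,1/min,turnover
pfk,a0,0.005,1/min,basal production
pfk,a_hif,0.01,1/min,HIF-driven production
pfk,a_myc,0.0042,1/min,MYC-driven production
pfk,km_hif,0.8,-,HIF response
pfk,km_myc,1.0,-,MYC response
pfk,kdeg,0.00833,1/min,turnover
protein,ktr,0.0333,1/min,translation toward gene level
protein,kdp,0.0333,1/min,protein turnover
protein,hk_base,0.5,-,MYC-scaled hexokinase target
protein,hk_myc,0.5,-,MYC-scaled hexokinase target
protein,hk_hif,1.0,-,HIF-driven hexokinase induction
protein,etc_p53,0.3,-,p53 support of respiratory capacity
protein,km_p53,1.5,-,p53 response
pool,nad_c,0.5,mM,cytosolic NAD pool
pool,nad_m,0.5,mM,mitochondrial NAD pool
pool,fad,0.1,mM,FAD pool
pool,adenylate,3.0,mM,ATP+ADP+AMP
pool,coa,0.15,mM,CoA pool
noise,sigma,0.01,1/sqrt(min),additive gene-expression noise
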